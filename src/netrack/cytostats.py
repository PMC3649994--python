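"""Zone-based cytological scoring and the associated statistics.

Covers the fixed-image side of the analyses: equal-length germline zone
assignment, FISH pairing calls with a two-tailed Fisher's exact test per zone,
diakinesis DAPI-body / bivalent accounting with two-tailed Mann-Whitney
comparisons, per-zone focus/patch/RAD-51 count histograms, HIM-8 / SC-stretch
association classes, and per-worm respiration normalization with a two-sample
t-test.

The karyotype arithmetic assumes 2n = 12: every chiasma-linked bivalent merges
two univalent bodies, so ``bodies = 2n - bivalents`` and a mean body count m
implies ``2n - m`` mean bivalents (6 bodies = 6 bivalents, 12 bodies = 12
univalents).

Mann-Whitney p-values are exact by enumeration for small samples -- oocyte
body counts are small integers with heavy ties, which the usual asymptotic
formula handles only via a tie-corrected normal approximation -- and switch
to that approximation for larger samples.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import ConfigurationError

#: Zone schemes: name -> number of zones.  "pairing-5" follows the pairing
#: survey (zones 2-6 along the gonad: premeiotic/transition entry through late
#: pachytene); "rad51-5" divides the transition-to-mid-pachytene region into
#: five equal-length zones.
ZONE_SCHEMES = {"pairing-5": 5, "rad51-5": 5}

#: Default bins for per-zone SUN-1 focus/patch count histograms.
DEFAULT_COUNT_BINS = ((0, 0), (1, 2), (3, 5), (6, 10), (11, None))

#: Inclusive 3D separation below which two FISH signals score as one focus.
DEFAULT_PAIRING_DIST_UM = 0.75


def assign_zones(positions: np.ndarray, n_zones: int = 5, scheme: str | None = None) -> np.ndarray:
    """Equal-length zone labels (1..n_zones) for normalized gonad positions.

    ``positions`` must lie in [0, 1]; position 1.0 belongs to the last zone.
    Passing a named ``scheme`` fixes ``n_zones`` to the scheme's count.
    """
    if scheme is not None:
        if scheme not in ZONE_SCHEMES:
            raise ConfigurationError(f"unknown zone scheme {scheme!r}")
        n_zones = ZONE_SCHEMES[scheme]
    if n_zones < 1:
        raise ConfigurationError("n_zones must be >= 1")
    pos = np.asarray(positions, dtype=float)
    if np.any(pos < 0) or np.any(pos > 1):
        raise ConfigurationError("positions must be normalized to [0, 1]")
    return np.minimum(np.floor(pos * n_zones).astype(int), n_zones - 1) + 1


def score_pairing(
    signal_coords_um: np.ndarray,
    merge_dist_um: float = DEFAULT_PAIRING_DIST_UM,
) -> str:
    """Pairing call for one nucleus from 1-2 FISH signal coordinates.

    One focus, or two foci within ``merge_dist_um`` (inclusive; 3D distance),
    scores ``paired``; two separated foci score ``unpaired``; more than two
    signals flag the nucleus for exclusion.
    """
    coords = np.atleast_2d(np.asarray(signal_coords_um, dtype=float))
    if len(coords) == 0:
        raise ConfigurationError("at least one signal coordinate required")
    if len(coords) > 2:
        warnings.warn(f"{len(coords)} signals in one nucleus; flagged for exclusion")
        return "excluded"
    if len(coords) == 1:
        return "paired"
    sep = float(np.linalg.norm(coords[0] - coords[1]))
    return "paired" if sep <= merge_dist_um else "unpaired"


def pairing_contingency_test(paired_a: int, n_a: int, paired_b: int, n_b: int) -> float:
    """Two-tailed Fisher's exact p for paired/unpaired counts in two groups."""
    if n_a <= 0 or n_b <= 0:
        raise ConfigurationError("group totals must be positive")
    if not (0 <= paired_a <= n_a and 0 <= paired_b <= n_b):
        raise ConfigurationError("paired counts must not exceed totals")
    table = [[paired_a, n_a - paired_a], [paired_b, n_b - paired_b]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def pairing_table_tests(zone_table: pd.DataFrame, other: pd.DataFrame) -> pd.DataFrame:
    """Per-zone Fisher tests between two genotypes' zone tables.

    Expects ``zone`` and boolean ``paired`` columns; returns one row per zone
    with counts, pairing percentages and the two-tailed p-value.  No
    multiple-testing correction is applied (per-zone p-values are reported raw).
    """
    rows = []
    for zone in sorted(set(zone_table["zone"]) | set(other["zone"])):
        a = zone_table[zone_table["zone"] == zone]
        b = other[other["zone"] == zone]
        if len(a) == 0 or len(b) == 0:
            rows.append({"zone": zone, "n_a": len(a), "n_b": len(b), "p": np.nan})
            continue
        pa, pb = int(a["paired"].sum()), int(b["paired"].sum())
        rows.append(
            {
                "zone": zone,
                "n_a": len(a),
                "n_b": len(b),
                "paired_pct_a": 100.0 * pa / len(a),
                "paired_pct_b": 100.0 * pb / len(b),
                "p": pairing_contingency_test(pa, len(a), pb, len(b)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# diakinesis accounting


def bivalents_from_bodies(mean_bodies: float, chromosome_number: int = 12) -> float:
    """Mean bivalents implied by a mean DAPI-body count.

    With ``bodies = bivalents + univalents`` and ``2*bivalents + univalents =
    2n``, the conversion is ``bivalents = 2n - bodies``; it is linear, so it
    holds for means as well as single oocytes.
    """
    if chromosome_number <= 0 or chromosome_number % 2:
        raise ConfigurationError("chromosome_number must be a positive even 2n")
    lo, hi = chromosome_number / 2.0, float(chromosome_number)
    if not lo <= mean_bodies <= hi:
        raise ConfigurationError(
            f"mean body count {mean_bodies} outside [{lo}, {hi}] for 2n={chromosome_number}"
        )
    return float(chromosome_number - mean_bodies)


def bodies_from_bivalents(mean_bivalents: float, chromosome_number: int = 12) -> float:
    """Inverse of :func:`bivalents_from_bodies` (the map is an involution pair)."""
    if not 0.0 <= mean_bivalents <= chromosome_number / 2.0:
        raise ConfigurationError("bivalent count outside [0, n]")
    return float(chromosome_number - mean_bivalents)


def _mann_whitney_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of sample x via midranks (ties shared)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_x = ranks[: len(x)].sum()
    return r_x - len(x) * (len(x) + 1) / 2.0


def _exact_mw_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all rank arrangements.

    Enumerates every way of splitting the pooled midranks into the two group
    sizes (ties handled exactly via shared midranks) and doubles the smaller
    one-sided tail, capped at 1 -- the standard permutation-test convention,
    which stays well defined when ties make the null distribution asymmetric.
    """
    n_x, n_y = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    observed = ranks[:n_x].sum()
    total = n_le = n_ge = 0
    for combo in itertools.combinations(range(n_x + n_y), n_x):
        u = ranks[list(combo)].sum()
        total += 1
        if u <= observed + 1e-9:
            n_le += 1
        if u >= observed - 1e-9:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


#: Per-group sample size at and below which the Mann-Whitney test enumerates
#: rank arrangements exactly (C(16,8) = 12870 arrangements at the limit).
MW_EXACT_MAX_N = 8


def compare_body_counts(sample_a, sample_b, exact_max_n: int = MW_EXACT_MAX_N) -> float:
    """Two-tailed Mann-Whitney p-value between two body-count samples.

    Exact enumeration (tie-aware) when both samples are small; otherwise the
    tie-corrected normal approximation.
    """
    x = np.asarray(sample_a, dtype=float)
    y = np.asarray(sample_b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ConfigurationError("each sample needs at least 2 observations")
    if max(len(x), len(y)) <= exact_max_n:
        return float(_exact_mw_p(x, y))
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                             use_continuity=False)
    return float(res.pvalue)


def estimate_chiasma_prob(bodies, chromosome_number: int = 12) -> float:
    """Method-of-moments chiasma probability from observed body counts."""
    bodies = np.asarray(bodies, dtype=float)
    n_pairs = chromosome_number // 2
    return float((chromosome_number - bodies.mean()) / n_pairs)


# ---------------------------------------------------------------------------
# count histograms


def count_category_histogram(
    zone_table: pd.DataFrame,
    category: str,
    bins=DEFAULT_COUNT_BINS,
) -> pd.DataFrame:
    """Per-zone percent-of-nuclei histogram of a count category.

    ``category`` selects the ``<category>_count`` column (e.g. ``focus``,
    ``patch``, ``rad51``).  ``bins`` are inclusive (lo, hi) count ranges, hi
    ``None`` meaning unbounded.  If a boolean ``<category>_stretch`` column is
    present, flagged nuclei are tallied in a separate ``stretch`` bin (used
    for elongated RAD-51 structures).  Fractions sum to 1 in every non-empty
    zone; empty zones are reported with n = 0.
    """
    col = f"{category}_count"
    if col not in zone_table.columns:
        raise ConfigurationError(f"zone table lacks column {col!r}")
    stretch_col = f"{category}_stretch"
    has_stretch = stretch_col in zone_table.columns
    labels = [_bin_label(lo, hi) for lo, hi in bins]
    rows = []
    for zone, sub in zone_table.groupby("zone"):
        n = len(sub)
        row = {"zone": zone, "n": n}
        stretch = sub[stretch_col].astype(bool) if has_stretch else pd.Series(False, index=sub.index)
        counted = sub[~stretch]
        for (lo, hi), lab in zip(bins, labels):
            hi_eff = np.inf if hi is None else hi
            frac = ((counted[col] >= lo) & (counted[col] <= hi_eff)).sum() / n if n else 0.0
            row[lab] = 100.0 * frac
        if has_stretch:
            row["stretch"] = 100.0 * stretch.sum() / n if n else 0.0
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values("zone").reset_index(drop=True)


def _bin_label(lo: int, hi: int | None) -> str:
    if hi is None:
        return f">{lo - 1}" if lo else "any"
    return str(lo) if lo == hi else f"{lo}-{hi}"


# ---------------------------------------------------------------------------
# HIM-8 / SC association


@dataclass
class SynapsisAssociation:
    him8_signal_count: int
    association_class: str


_POINT = tuple[float, float]


def _point_to_polyline_um(point: np.ndarray, polyline: np.ndarray) -> float:
    p = np.asarray(point, dtype=float)
    v = np.asarray(polyline, dtype=float)
    if len(v) == 1:
        return float(np.linalg.norm(p - v[0]))
    a, b = v[:-1], v[1:]
    ab = b - a
    t = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.einsum("ij,ij->i", ab, ab), 0, 1)
    proj = a + t[:, None] * ab
    return float(np.min(np.linalg.norm(p - proj, axis=1)))


def classify_synapsis_association(
    him8_coords_um,
    sc_polylines_um,
    assoc_dist_um: float = 0.3,
) -> SynapsisAssociation:
    """Class of HIM-8 signal(s) relative to SC (SYP-1) stretches.

    A signal associates with the nearest stretch within ``assoc_dist_um`` of
    its polyline.  Classes: ``single-SC-paired`` (one signal, on a stretch),
    ``both-on-different-SC``, ``both-on-same-SC``, ``one-on-SC``,
    ``none-on-SC``.
    """
    coords = np.atleast_2d(np.asarray(him8_coords_um, dtype=float))
    if len(coords) not in (1, 2):
        raise ConfigurationError("expected 1 or 2 HIM-8 signals")
    nearest: list[int | None] = []
    for c in coords:
        best_i, best_d = None, math.inf
        for i, poly in enumerate(sc_polylines_um):
            d = _point_to_polyline_um(c, np.asarray(poly))
            if d < best_d:
                best_i, best_d = i, d
        nearest.append(best_i if best_d <= assoc_dist_um else None)
    if len(coords) == 1:
        cls = "single-SC-paired" if nearest[0] is not None else "none-on-SC"
    else:
        on = [i for i in nearest if i is not None]
        if len(on) == 2:
            cls = "both-on-different-SC" if nearest[0] != nearest[1] else "both-on-same-SC"
        elif len(on) == 1:
            cls = "one-on-SC"
        else:
            cls = "none-on-SC"
    return SynapsisAssociation(him8_signal_count=len(coords), association_class=cls)


def summarize_associations(associations) -> pd.Series:
    """Tally association classes over nuclei (e.g. a 37-of-40-style count)."""
    return pd.Series([a.association_class for a in associations]).value_counts()


# ---------------------------------------------------------------------------
# respiration


def normalize_respiration(records: pd.DataFrame, genotype_col: str = "genotype") -> dict:
    """Per-worm respiration rates and a two-sample t-test between genotypes.

    ``records`` needs one row per well with ``worms_in_well``, a genotype
    label, and measurement columns ``ocr_1`` .. ``ocr_7`` (seven oxygen
    consumption readings per well).  The per-well rate is the mean of the
    seven readings divided by the worm count; genotypes are compared by a
    two-sided two-sample t-test over well replicates, with the SEM across
    wells reported per genotype.
    """
    meas_cols = [c for c in records.columns if c.startswith("ocr_")]
    if len(meas_cols) != 7:
        raise ConfigurationError("expected exactly 7 ocr_* measurement columns")
    if (records["worms_in_well"] <= 0).any():
        raise ConfigurationError("worms_in_well must be positive")
    rates = records[meas_cols].mean(axis=1) / records["worms_in_well"]
    out = records[[genotype_col, "well_id", "worms_in_well"]].copy()
    out["per_worm_rate"] = rates
    groups = out.groupby(genotype_col)["per_worm_rate"]
    summary = groups.agg(["mean", "sem", "count"])
    names = list(summary.index)
    p = None
    if len(names) == 2:
        a = out.loc[out[genotype_col] == names[0], "per_worm_rate"]
        b = out.loc[out[genotype_col] == names[1], "per_worm_rate"]
        p = float(stats.ttest_ind(a, b).pvalue)
    return {"rates": out, "summary": summary, "p": p}
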