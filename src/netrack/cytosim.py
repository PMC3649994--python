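"""Synthetic cytology tables: diakinesis body counts and germline zone scores.

The oocyte model is deliberately minimal: with six chromosome pairs (2n = 12),
each pair independently forms a chiasma with probability ``chiasma_prob``, so
the bivalent count per oocyte is Binomial(6, p) and the number of DAPI-stained
bodies is ``2n − bivalents`` (a bivalent merges two univalent bodies into one).
Zone tables draw per-nucleus Bernoulli pairing calls and categorical
focus/patch counts with zone-specific parameters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CytoSimConfig
from .models import ConfigurationError

#: Default per-zone SUN-1 focus/patch count distributions.  Values are counts,
#: probabilities sum to 1 per zone.  The wild-type-like table concentrates a
#: few patches per nucleus; the mutant-like table shifts zone-3 nuclei toward
#: 6-10 small foci and keeps aggregates around into later zones.
WT_LIKE_FOCI_DIST = {
    "focus": ((0, 1, 2, 3), (0.55, 0.25, 0.15, 0.05)),
    "patch": ((0, 1, 2, 3, 4), (0.05, 0.15, 0.35, 0.30, 0.15)),
}
SPD3_LIKE_FOCI_DIST = {
    "focus": ((2, 4, 6, 7, 8, 9, 10, 12), (0.08, 0.12, 0.14, 0.14, 0.12, 0.10, 0.10, 0.20)),
    "patch": ((0, 1, 2), (0.55, 0.35, 0.10)),
}


def simulate_oocyte_counts(
    config: CytoSimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-oocyte bivalent and DAPI-body counts under the binomial chiasma model."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_pairs = config.chromosome_number // 2
    bivalents = rng.binomial(n_pairs, config.chiasma_prob, size=config.n_oocytes)
    return pd.DataFrame(
        {
            "oocyte_id": np.arange(config.n_oocytes),
            "bivalents": bivalents,
            "bodies": config.chromosome_number - bivalents,
        }
    )


def simulate_zone_scores(
    config: CytoSimConfig,
    rng: np.random.Generator | None = None,
    foci_count_dist: dict | None = None,
) -> pd.DataFrame:
    """Per-nucleus zone table: pairing call plus focus/patch counts.

    Zones are numbered 1..n_zones following the germline axis.  The optional
    ``foci_count_dist`` maps category -> (values, probs) or category -> list of
    per-zone (values, probs); it falls back to ``config.foci_count_dist`` and
    then to a wild-type-like default.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    dist = foci_count_dist or config.foci_count_dist or WT_LIKE_FOCI_DIST
    n_zones = config.n_zones
    rows = []
    nucleus_id = 0
    for zi, p_pair in enumerate(config.pairing_prob_by_zone, start=1):
        for _ in range(config.n_nuclei_per_zone):
            row = {
                "nucleus_id": nucleus_id,
                "zone": zi,
                "position": (zi - 0.5) / n_zones,
                "paired": bool(rng.random() < p_pair),
            }
            for cat, spec in dist.items():
                values, probs = spec[zi - 1] if _per_zone(spec, n_zones) else spec
                probs = np.asarray(probs, dtype=float)
                if abs(probs.sum() - 1.0) > 1e-9:
                    raise ConfigurationError(f"probabilities for {cat!r} must sum to 1")
                row[f"{cat}_count"] = int(rng.choice(values, p=probs))
            rows.append(row)
            nucleus_id += 1
    return pd.DataFrame(rows)


def _per_zone(spec, n_zones: int) -> bool:
    """True when a distribution spec is a per-zone list rather than (values, probs)."""
    if len(spec) == n_zones and all(
        isinstance(s, (tuple, list)) and len(s) == 2 and np.ndim(s[0]) == 1 for s in spec
    ):
        return True
    if len(spec) != 2:
        raise ConfigurationError(
            "foci_count_dist entries must be (values, probs) or one such pair per zone"
        )
    return False
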