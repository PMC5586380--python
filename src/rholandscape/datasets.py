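"""Small published reference tables bundled for map comparison.

``mouse_chromosome_rates`` returns per-chromosome sex-averaged recombination
rates for house mouse: genetic-map lengths expressed as cM/Mb from the Cox
et al. (2009) pedigree-based linkage map, alongside frequency-weighted mean
scaled rates (rho/bp = 4*Ne*r) from an LD-based map of wild Mus musculus
castaneus and from the Brunschwig et al. (2012) LD-based map of classical
inbred strains.  These are the standard anchor/comparison inputs for
broad-scale validation of a new mouse map.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["mouse_chromosome_rates", "cox_anchors"]

# chromosome, Cox cM/Mb, castaneus rho/bp, Brunschwig rho/bp
_CHROMOSOME_RATES = [
    ("1", 0.50, 0.0079, 0.000015),
    ("2", 0.57, 0.0088, 0.000015),
    ("3", 0.52, 0.0083, 0.000014),
    ("4", 0.56, 0.0091, 0.000020),
    ("5", 0.59, 0.0090, 0.000015),
    ("6", 0.53, 0.0089, 0.000015),
    ("7", 0.58, 0.0100, 0.000019),
    ("8", 0.58, 0.0094, 0.000014),
    ("9", 0.61, 0.0096, 0.000018),
    ("10", 0.61, 0.0096, 0.000023),
    ("11", 0.70, 0.0102, 0.000019),
    ("12", 0.53, 0.0089, 0.000019),
    ("13", 0.56, 0.0095, 0.000014),
    ("14", 0.53, 0.0084, 0.000013),
    ("15", 0.56, 0.0083, 0.000024),
    ("16", 0.59, 0.0091, 0.000017),
    ("17", 0.65, 0.0087, 0.000052),
    ("18", 0.66, 0.0098, 0.000021),
    ("19", 0.94, 0.0122, 0.000026),
    ("X", 0.48, 0.0026, None),
]


def mouse_chromosome_rates(include_x: bool = True) -> pd.DataFrame:
    """Per-chromosome recombination-rate comparison table for house mouse.

    Columns: ``chromosome``, ``cox_cm_per_mb`` (pedigree linkage map),
    ``castaneus_rho_per_bp`` (LD-based, wild M. m. castaneus),
    ``brunschwig_rho_per_bp`` (LD-based, classical strains; no X estimate).
    """
    df = pd.DataFrame(
        _CHROMOSOME_RATES,
        columns=[
            "chromosome",
            "cox_cm_per_mb",
            "castaneus_rho_per_bp",
            "brunschwig_rho_per_bp",
        ],
    )
    if not include_x:
        df = df[df["chromosome"] != "X"].reset_index(drop=True)
    return df


def cox_anchors() -> dict[str, float]:
    """Cox-map cM/Mb per chromosome, as a plain dict keyed by chromosome."""
    return {row[0]: row[1] for row in _CHROMOSOME_RATES}
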