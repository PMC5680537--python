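"""Mutation-panel definition files.

A panel file is tab-delimited with two columns, ``mutation_id`` and
``population_share`` — the fraction of all CFTR mutant alleles in the
screened population attributable to that mutation.  The panel *coverage*
``a`` is the column sum: the probability that a random mutant allele is
detectable by the panel.  A 23-mutation fixture mirroring the pan-ethnic
ACMG carrier-testing panel is bundled; its per-mutation shares are synthetic
(illustrative) but sum to the panel's published coverage, 0.834, which is
the only quantity the screening model consumes.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["read_panel", "panel_coverage", "bundled_acmg23_panel_path"]

_BUNDLED = "acmg23_panel_synthetic.tsv"


def bundled_acmg23_panel_path() -> Path:
    """Path to the bundled synthetic ACMG-23 panel fixture."""
    return Path(resources.files("cfscreen").joinpath("data", _BUNDLED))


def read_panel(path: str | Path | None = None) -> pd.DataFrame:
    """Read a panel definition file (default: the bundled ACMG-23 fixture).

    Returns a DataFrame with columns ``mutation_id`` (str) and
    ``population_share`` (float).  Raises ``ValueError`` for an empty panel,
    duplicated mutation ids, or shares outside (0, 1] / summing above 1.
    """
    if path is None:
        path = bundled_acmg23_panel_path()
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"mutation_id": str})
    required = {"mutation_id", "population_share"}
    if not required.issubset(df.columns):
        raise ValueError(f"panel file must have columns {sorted(required)}")
    if len(df) == 0:
        raise ValueError("panel file defines no mutations")
    if df["mutation_id"].duplicated().any():
        raise ValueError("panel file contains duplicated mutation ids")
    shares = df["population_share"].astype(float)
    if (shares <= 0).any() or (shares > 1).any():
        raise ValueError("population_share values must lie in (0, 1]")
    if shares.sum() > 1.0 + 1e-9:
        raise ValueError("population_share column sums above 1")
    df = df.copy()
    df["population_share"] = shares
    return df


def panel_coverage(panel: pd.DataFrame) -> float:
    """Panel coverage ``a``: the sum of the population shares."""
    return float(panel["population_share"].sum())
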