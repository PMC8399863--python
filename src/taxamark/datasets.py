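"""Packaged reference tables for the *L. plantarum* species-group case study.

Three small published tables ship with the package: the pairwise percent
identities of *mutL* and of the 16S rRNA gene among the group's 17 type
strains, and the *mutL*-targeting primer set (one degenerate group-level
pair, four species-specific diagnostic pairs with their reported amplicon
sizes).  They serve as worked-example inputs and as fixed points for the
identity-statistics and primer stages.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .markerrank import IdentityMatrix

__all__ = [
    "mutl_type_strain_identities",
    "rrna16s_type_strain_identities",
    "plantarum_group_primers",
]

_DATA = files("taxamark") / "data"


def mutl_type_strain_identities() -> IdentityMatrix:
    """Published *mutL* percent identities among the 17 type strains."""
    with (_DATA / "plantarum_group_mutl_identities.tsv").open() as fh:
        return IdentityMatrix.from_tsv(fh)


def rrna16s_type_strain_identities() -> IdentityMatrix:
    """Published 16S rRNA percent identities among the 17 type strains."""
    with (_DATA / "plantarum_group_16s_identities.tsv").open() as fh:
        return IdentityMatrix.from_tsv(fh)


def plantarum_group_primers() -> pd.DataFrame:
    """The published primer set (columns: assay, target, forward, reverse,
    expected_product)."""
    with (_DATA / "plantarum_group_primers.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
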