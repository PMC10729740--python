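"""Clonotype records and AIRR-style tabular I/O.

A clonotype is a unique paired alpha/beta TCR: the amino-acid CDR3 junctions
plus V/J gene calls for both chains.  Cells sharing a clonotype descend from a
single V(D)J recombination event, so the clonotype is the natural unit for
sequence-level analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import SequenceError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Column order of the AIRR-style clonotype table written/read by this package.
AIRR_COLUMNS = [
    "clonotype_id",
    "patient_id",
    "junction_aa_alpha",
    "junction_aa_beta",
    "v_call_alpha",
    "j_call_alpha",
    "v_call_beta",
    "j_call_beta",
    "antigen",
]


@dataclass(frozen=True)
class ClonotypeRecord:
    """One paired-chain TCR clonotype with gene calls and provenance."""

    clonotype_id: str
    patient_id: str
    cdr3a: str
    cdr3b: str
    va: str
    ja: str
    vb: str
    jb: str
    antigen: str = ""

    def __post_init__(self) -> None:
        for chain, seq in (("alpha", self.cdr3a), ("beta", self.cdr3b)):
            if not seq:
                raise SequenceError(f"empty CDR3 {chain} sequence for {self.clonotype_id}")
            for pos, aa in enumerate(seq):
                if aa not in AA_ALPHABET:
                    raise SequenceError(
                        f"unknown amino acid {aa!r} at position {pos} of CDR3 "
                        f"{chain} in clonotype {self.clonotype_id}"
                    )
        for name, gene in (("va", self.va), ("ja", self.ja), ("vb", self.vb), ("jb", self.jb)):
            if not gene:
                raise SequenceError(f"empty gene call {name} for {self.clonotype_id}")


def clonotypes_to_frame(records: list[ClonotypeRecord]) -> pd.DataFrame:
    """Tabulate clonotypes into an AIRR-style data frame."""
    return pd.DataFrame(
        {
            "clonotype_id": [r.clonotype_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "junction_aa_alpha": [r.cdr3a for r in records],
            "junction_aa_beta": [r.cdr3b for r in records],
            "v_call_alpha": [r.va for r in records],
            "j_call_alpha": [r.ja for r in records],
            "v_call_beta": [r.vb for r in records],
            "j_call_beta": [r.jb for r in records],
            "antigen": [r.antigen for r in records],
        }
    )


def frame_to_clonotypes(df: pd.DataFrame) -> list[ClonotypeRecord]:
    """Build clonotype records from an AIRR-style table (inverse of
    :func:`clonotypes_to_frame`; extra columns are ignored)."""
    return [
        ClonotypeRecord(
            clonotype_id=str(row["clonotype_id"]),
            patient_id=str(row["patient_id"]),
            cdr3a=str(row["junction_aa_alpha"]),
            cdr3b=str(row["junction_aa_beta"]),
            va=str(row["v_call_alpha"]),
            ja=str(row["j_call_alpha"]),
            vb=str(row["v_call_beta"]),
            jb=str(row["j_call_beta"]),
            antigen=str(row.get("antigen", "")) if "antigen" in df.columns else "",
        )
        for _, row in df.iterrows()
    ]


def read_airr(path) -> list[ClonotypeRecord]:
    """Read an AIRR-style TSV of paired-chain clonotypes."""
    return frame_to_clonotypes(pd.read_csv(path, sep="\t", dtype=str))


def write_airr(records: list[ClonotypeRecord], path) -> None:
    """Write clonotypes as an AIRR-style TSV."""
    clonotypes_to_frame(records).to_csv(path, sep="\t", index=False)
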