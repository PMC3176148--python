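"""Protein alignment I/O and sequence-level utilities.

The central container is :class:`AlignedProteinSet`, a validated protein
multiple sequence alignment (MSA) with per-sequence species metadata.  All
evolutionary distances in the package are computed over such a set.

Sequence-level helpers cover the two standard preprocessing steps for plant
acyl-ACP thioesterases: locating the mature protein by the conserved ``LPDW``
plastid transit-peptide cleavage anchor, and computing molecular weight and
theoretical isoelectric point of pre- and mature proteins.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, TEClassError

#: Canonical amino acids, in the conventional one-letter ordering used by the
#: JTT model tables (A R N D C Q E G H I L K M F P S T W Y V).
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Ambiguity / special codes retained on read and treated as missing data
#: downstream (pairwise deletion removes them together with gaps).
AMBIGUITY_CODES = "BZXJUO*"

GAP = "-"

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    species: str
    sequence: str


@dataclass
class AlignedProteinSet:
    """A validated protein MSA plus per-sequence species labels.

    Invariants (checked on construction): at least one record, unique ids,
    all sequences the same positive length, and every character either a
    canonical residue, a gap, or a recognized ambiguity code.
    """

    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("alignment contains no sequences")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            ref = len(self.records[0].sequence)
            bad = next(r for r in self.records if len(r.sequence) != ref)
            raise AlignmentError(
                f"ragged alignment: sequence {bad.id!r} has length "
                f"{len(bad.sequence)} but expected {ref}"
            )
        if lengths == {0}:
            raise AlignmentError("alignment has zero columns")
        seen: set[str] = set()
        for r in self.records:
            if r.id in seen:
                raise AlignmentError(f"duplicate sequence id {r.id!r}")
            seen.add(r.id)
        valid = set(AMINO_ACIDS + AMBIGUITY_CODES + GAP)
        for r in self.records:
            bad_chars = set(r.sequence.upper()) - valid
            if bad_chars:
                raise AlignmentError(
                    f"sequence {r.id!r} contains invalid characters "
                    f"{sorted(bad_chars)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, seq_id: str) -> ProteinRecord:
        for r in self.records:
            if r.id == seq_id:
                return r
        raise KeyError(seq_id)

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.records[0].sequence)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def species(self) -> list[str]:
        return [r.species for r in self.records]

    def encoded(self) -> np.ndarray:
        """Integer-encode the alignment (n x L).

        Canonical residues map to 0..19 in JTT table order; gaps and
        ambiguity codes map to -1 (missing under pairwise deletion).
        """
        n, L = len(self.records), self.length
        out = np.full((n, L), -1, dtype=np.int8)
        for i, r in enumerate(self.records):
            for j, ch in enumerate(r.sequence.upper()):
                out[i, j] = _AA_INDEX.get(ch, -1)
        return out

    def subset_columns(self, columns: Sequence[int]) -> "AlignedProteinSet":
        cols = list(columns)
        recs = [
            ProteinRecord(r.id, r.species, "".join(r.sequence[c] for c in cols))
            for r in self.records
        ]
        return AlignedProteinSet(recs)

    def subset_ids(self, ids: Iterable[str]) -> "AlignedProteinSet":
        wanted = set(ids)
        return AlignedProteinSet([r for r in self.records if r.id in wanted])


def _default_species_parser(header: str) -> tuple[str, str]:
    """Split a FASTA header into (id, species).

    Default convention: text after the first ``|`` is the species; if there
    is no ``|`` the whole header doubles as the species label.
    """
    header = header.strip()
    if "|" in header:
        seq_id, species = header.split("|", 1)
        return seq_id.strip(), species.strip()
    return header.split()[0], header


def read_msa(
    path: str | Path,
    species_parser: Callable[[str], tuple[str, str]] | None = None,
) -> AlignedProteinSet:
    """Read a protein MSA from an aligned FASTA file.

    Gap and ambiguity characters are preserved verbatim.  Raises
    :class:`AlignmentError` for an empty file, ragged alignment, duplicate
    ids, or invalid residue characters.
    """
    parser = species_parser or _default_species_parser
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq_id, species = parser(rec.description)
        records.append(ProteinRecord(seq_id, species, str(rec.seq)))
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return AlignedProteinSet(records)


def write_msa(aln: AlignedProteinSet, path: str | Path) -> None:
    """Write the alignment as FASTA with ``>id|species`` headers."""
    recs = [
        SeqRecord(Seq(r.sequence), id=f"{r.id}|{r.species}", description="")
        for r in aln.records
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Transit-peptide cleavage
# ---------------------------------------------------------------------------

def cleave_transit_peptide(sequence: str, motif: str = "LPDW") -> str | None:
    """Strip the N-terminal plastid transit peptide at the conserved motif.

    Plant acyl-ACP thioesterases are nuclear-encoded, plastid-targeted
    proteins; the mature protein is taken to begin at the first occurrence
    of the conserved ``LPDW`` anchor (its leucine is the putative mature
    N-terminus).  Returns the suffix starting at the motif, or ``None`` when
    the motif is absent — never a silent truncation.
    """
    if not sequence:
        raise TEClassError("empty sequence")
    idx = sequence.find(motif)
    if idx < 0:
        return None
    return sequence[idx:]


# ---------------------------------------------------------------------------
# Molecular weight and theoretical pI
# ---------------------------------------------------------------------------

# Average and monoisotopic residue masses are taken from Biopython's tables
# (free amino acid masses; one water is subtracted per peptide bond).
from Bio.Data.IUPACData import (  # noqa: E402
    protein_weights as _AVG_AA_WEIGHTS,
    monoisotopic_protein_weights as _MONO_AA_WEIGHTS,
)

_WATER_AVG = 18.0153
_WATER_MONO = 18.010565

#: Bjellqvist pKa values (the set used by ExPASy-style "theoretical pI"
#: calculators).  Keys: side chains plus terminal groups; N/C-terminal pKas
#: are residue-specific where published.
BJELLQVIST = {
    "positive": {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98},
    "negative": {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    "nterm_by_residue": {
        "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44,
        "E": 7.7,
    },
    "cterm_by_residue": {"D": 4.55, "E": 4.75},
}


@dataclass(frozen=True)
class ProteinProperties:
    length: int
    molecular_weight: float  # Da
    isoelectric_point: float  # pH units


def net_charge(sequence: str, pH: float, pka_set: dict = BJELLQVIST) -> float:
    """Net charge of a peptide at a given pH under the chosen pKa set."""
    pos = pka_set["positive"]
    neg = pka_set["negative"]
    counts = {aa: sequence.count(aa) for aa in set(sequence)}
    charge = 0.0
    nterm_pk = pka_set.get("nterm_by_residue", {}).get(sequence[0], pos["Nterm"])
    charge += 1.0 / (1.0 + 10 ** (pH - nterm_pk))
    cterm_pk = pka_set.get("cterm_by_residue", {}).get(sequence[-1], neg["Cterm"])
    charge -= 1.0 / (1.0 + 10 ** (cterm_pk - pH))
    for aa, pk in pos.items():
        if aa == "Nterm":
            continue
        charge += counts.get(aa, 0) / (1.0 + 10 ** (pH - pk))
    for aa, pk in neg.items():
        if aa == "Cterm":
            continue
        charge -= counts.get(aa, 0) / (1.0 + 10 ** (pk - pH))
    return charge


def protein_properties(
    sequence: str,
    pka_set: dict = BJELLQVIST,
    monoisotopic: bool = False,
) -> ProteinProperties:
    """Length, molecular weight and theoretical pI of a protein.

    MW is the sum of residue masses plus one water (average masses by
    default).  The pI is the pH at which :func:`net_charge` crosses zero,
    found by bisection on [0, 14] to 1e-4 pH units.  The net-charge model is
    monotone decreasing in pH, so the bracketing root is unique.
    """
    if not sequence:
        raise TEClassError("empty sequence")
    sequence = sequence.upper()
    bad = sorted(set(sequence) - set(AMINO_ACIDS))
    if bad:
        raise TEClassError(f"non-canonical residues in sequence: {bad}")
    table = _MONO_AA_WEIGHTS if monoisotopic else _AVG_AA_WEIGHTS
    water = _WATER_MONO if monoisotopic else _WATER_AVG
    mw = sum(table[aa] - water for aa in sequence) + water
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-4:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return ProteinProperties(len(sequence), mw, 0.5 * (lo + hi))


def properties_table(
    aln_or_records: AlignedProteinSet | Iterable[ProteinRecord],
    cleave: bool = False,
    motif: str = "LPDW",
):
    """Tabulate (id, length, MW_Da, pI) for a set of sequences.

    With ``cleave=True`` the transit peptide is removed first; sequences
    lacking the motif are reported with ``NA`` properties.
    """
    import pandas as pd

    records = (
        aln_or_records.records
        if isinstance(aln_or_records, AlignedProteinSet)
        else list(aln_or_records)
    )
    rows = []
    for rec in records:
        seq = rec.sequence.replace(GAP, "")
        if cleave:
            seq = cleave_transit_peptide(seq, motif)
        if seq is None:
            rows.append({"id": rec.id, "length": None, "MW_Da": None, "pI": None})
            continue
        props = protein_properties(seq)
        rows.append(
            {
                "id": rec.id,
                "length": props.length,
                "MW_Da": round(props.molecular_weight, 2),
                "pI": round(props.isoelectric_point, 2),
            }
        )
    return pd.DataFrame(rows)
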