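"""Lysine-centered peptide window extraction.

Candidate succinylation sites are lysines (K). Each site is represented by a
fixed-length fragment of ``2r + 1`` residues centered on the lysine, with
``r`` residues taken upstream and downstream. Fragments truncated by a
protein terminus are padded with ``'X'`` (the conventional ambiguity letter)
to full length; pad counts are recorded so downstream encoders can treat
padded positions as missing data.

Coordinates are 1-based in all user-facing I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

#: The 20 standard amino acids in PSI-BLAST column order. This is the
#: canonical residue order used throughout the package (feature naming,
#: PSSM columns, property tables).
STANDARD_AA = "ARNDCQEGHILKMFPSTWYV"

#: Ambiguity / non-standard letters tolerated in input sequences.
AMBIGUOUS_AA = "BZUXOJ"

#: Character used to pad windows that overhang a protein terminus.
PAD_CHAR = "X"

VALID_ALPHABET = frozenset(STANDARD_AA + AMBIGUOUS_AA)

#: Default window radius: 10 residues either side of the central lysine,
#: giving 21-mer fragments.
DEFAULT_RADIUS = 10

POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a dataset-unique identifier."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residue letters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SiteLabel:
    """A labeled candidate site: 1-based lysine position in a protein."""

    protein_id: str
    position: int
    label: str

    def __post_init__(self) -> None:
        if self.label not in (POSITIVE, NEGATIVE):
            raise ValueError(f"label must be positive/negative, got {self.label!r}")


@dataclass(frozen=True)
class PeptideWindow:
    """A ``2r + 1``-mer centered on a candidate lysine.

    ``n_pad_left`` / ``n_pad_right`` count 'X' characters added where the
    window overhangs the protein N- or C-terminus.
    """

    protein_id: str
    center_position: int
    residues: str
    n_pad_left: int = 0
    n_pad_right: int = 0
    label: str | None = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.residues)
        if n % 2 != 1:
            raise ValueError(f"window length must be odd, got {n}")
        if self.n_pad_left + self.n_pad_right >= n:
            raise ValueError("window is entirely padding")

    @property
    def radius(self) -> int:
        return len(self.residues) // 2

    @property
    def center_residue(self) -> str:
        return self.residues[self.radius]


def _window_at(protein: ProteinRecord, position: int, r: int,
               label: str | None) -> PeptideWindow:
    seq = protein.sequence
    i = position - 1  # 0-based center
    lo, hi = i - r, i + r + 1
    n_pad_left = max(0, -lo)
    n_pad_right = max(0, hi - len(seq))
    core = seq[max(lo, 0):min(hi, len(seq))]
    return PeptideWindow(
        protein_id=protein.id,
        center_position=position,
        residues=PAD_CHAR * n_pad_left + core + PAD_CHAR * n_pad_right,
        n_pad_left=n_pad_left,
        n_pad_right=n_pad_right,
        label=label,
    )


def extract_windows(protein: ProteinRecord, sites: Iterable[SiteLabel],
                    r: int = DEFAULT_RADIUS) -> list[PeptideWindow]:
    """Extract one labeled window per site, in input order.

    Raises
    ------
    ValueError
        If a site position falls outside the sequence or does not point at
        a lysine. A mislabeled site is a hard error, never a silent skip:
        silently relabeling or dropping sites would corrupt training data.
    """
    windows: list[PeptideWindow] = []
    for site in sites:
        if site.protein_id != protein.id:
            raise ValueError(
                f"site for protein {site.protein_id!r} applied to {protein.id!r}"
            )
        if not 1 <= site.position <= len(protein):
            raise ValueError(
                f"protein {protein.id!r}: site position {site.position} outside "
                f"sequence of length {len(protein)}"
            )
        residue = protein.sequence[site.position - 1]
        if residue != "K":
            raise ValueError(
                f"protein {protein.id!r}: residue at position {site.position} "
                f"is {residue!r}, expected 'K'"
            )
        windows.append(_window_at(protein, site.position, r, site.label))
    return windows


def scan_all_lysines(protein: ProteinRecord,
                     r: int = DEFAULT_RADIUS) -> list[PeptideWindow]:
    """One unlabeled window per lysine in the sequence (prediction mode)."""
    return [
        _window_at(protein, i + 1, r, None)
        for i, residue in enumerate(protein.sequence)
        if residue == "K"
    ]


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA file; '*' stop characters are stripped."""
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate protein id {rec.id!r}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, str(rec.seq).upper().replace("*", "")))
    return records


def read_site_table(path: str | Path) -> list[SiteLabel]:
    """Read a site list TSV: protein_id, 1-based position, label in {1, 0}.

    A header line is detected (non-integer second column) and skipped.
    """
    sites: list[SiteLabel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            pid, pos_s, lab_s = (p.strip() for p in parts)
            if lineno == 1 and not pos_s.lstrip("-").isdigit():
                continue  # header
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer position {pos_s!r}") from None
            if lab_s not in ("0", "1"):
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {lab_s!r}")
            sites.append(SiteLabel(pid, pos, POSITIVE if lab_s == "1" else NEGATIVE))
    return sites


def write_site_table(sites: Iterable[SiteLabel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tposition\tlabel\n")
        for s in sites:
            fh.write(f"{s.protein_id}\t{s.position}\t{1 if s.label == POSITIVE else 0}\n")
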