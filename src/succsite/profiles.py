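"""Readers for per-protein profile files and window-local slicing.

Two profile kinds accompany each protein:

* the ASCII position-specific scoring matrix written by PSI-BLAST with
  ``-out_ascii_pssm`` — per-residue rows of 20 log-odds conservation scores
  followed by 20 weighted observed percentages (the PSFM);
* a per-residue intrinsic-disorder table (as produced by VSL2B-style
  predictors): residue index, residue letter, score in [0, 1].

Profiles are sliced to 21-row window-local matrices aligned with the peptide
windows; positions padded at a terminus get all-zero PSSM rows and disorder
score 0.0 (zero is the neutral element for both the flatten and the mean
features downstream).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .windows import PeptideWindow, STANDARD_AA


class ProfileParseError(ValueError):
    """Malformed profile file; message carries path and line number."""


@dataclass(frozen=True)
class PSSMProfile:
    """Protein-length conservation profile.

    ``scores``: L×20 log-odds matrix, columns in canonical AA order
    (:data:`succsite.windows.STANDARD_AA`). ``frequencies``: optional L×20
    position-specific frequency matrix with values in [0, 1].
    """

    protein_id: str
    scores: np.ndarray
    frequencies: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(f"scores must be L×20, got {self.scores.shape}")
        if self.frequencies is not None and self.frequencies.shape != self.scores.shape:
            raise ValueError("frequencies shape must match scores")

    def __len__(self) -> int:
        return self.scores.shape[0]


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue disorder scores in [0, 1], one per residue."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        s = self.scores
        if s.ndim != 1:
            raise ValueError("disorder scores must be 1-D")
        if np.any((s < 0) | (s > 1)):
            raise ValueError(f"protein {self.protein_id!r}: disorder scores outside [0, 1]")

    def __len__(self) -> int:
        return self.scores.shape[0]


def read_ascii_pssm(path: str | Path, protein_id: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    The 20 log-odds columns become ``scores``; the 20 percentage columns,
    divided by 100, become ``frequencies``. Column order is taken from the
    file's header line and remapped to canonical AA order so features are
    stable across PSI-BLAST versions.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    with open(path) as fh:
        lines = fh.readlines()

    header_idx = None
    col_order: list[str] = []
    for i, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) >= 40 and all(t in STANDARD_AA for t in tokens[:40]):
            header_idx = i
            col_order = tokens[:20]
            break
    if header_idx is None:
        raise ProfileParseError(f"{path}: no PSSM column header line found")
    if sorted(col_order) != sorted(STANDARD_AA):
        raise ProfileParseError(
            f"{path}:{header_idx + 1}: header does not list the 20 standard amino acids"
        )

    score_rows: list[list[float]] = []
    freq_rows: list[list[float]] = []
    expected_index = 1
    for lineno0 in range(header_idx + 1, len(lines)):
        line = lines[lineno0]
        tokens = line.split()
        if not tokens:
            break  # blank line ends the matrix block
        if not tokens[0].lstrip("-").isdigit():
            break  # trailing statistics (K, Lambda) block
        lineno = lineno0 + 1
        if int(tokens[0]) != expected_index:
            raise ProfileParseError(
                f"{path}:{lineno}: residue index {tokens[0]} out of order "
                f"(expected {expected_index})"
            )
        if len(tokens) < 42:
            raise ProfileParseError(
                f"{path}:{lineno}: expected index, residue and 40 numeric columns, "
                f"got {len(tokens)} fields"
            )
        try:
            numbers = [float(t) for t in tokens[2:42]]
        except ValueError as exc:
            raise ProfileParseError(f"{path}:{lineno}: non-numeric matrix entry ({exc})") from None
        score_rows.append(numbers[:20])
        freq_rows.append(numbers[20:40])
        expected_index += 1

    if not score_rows:
        raise ProfileParseError(f"{path}: file contains no matrix rows")

    # remap file column order -> canonical order
    perm = [col_order.index(aa) for aa in STANDARD_AA]
    scores = np.asarray(score_rows, dtype=float)[:, perm]
    freqs = np.asarray(freq_rows, dtype=float)[:, perm] / 100.0
    return PSSMProfile(protein_id=protein_id, scores=scores, frequencies=freqs)


def write_ascii_pssm(profile: PSSMProfile, path: str | Path,
                     sequence: str | None = None) -> None:
    """Write a profile in the PSI-BLAST ``-out_ascii_pssm`` dialect.

    Scores are written as integers (rounded) and frequencies as whole
    percentages, matching what PSI-BLAST itself emits; this writer doubles
    as the format documentation for :func:`read_ascii_pssm`.
    """
    scores = profile.scores
    freqs = profile.frequencies
    if freqs is None:
        freqs = np.zeros_like(scores)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed, weighted "
                 "observed percentages rounded down, information per position, "
                 "and relative weight of gapless real matches to pseudocounts\n")
        header = "      " + "  ".join(f"{aa:>2}" for aa in STANDARD_AA)
        fh.write(header + "  " + "  ".join(f"{aa:>2}" for aa in STANDARD_AA) + "\n")
        for i in range(scores.shape[0]):
            residue = sequence[i] if sequence else "X"
            row = f"{i + 1:>5} {residue} "
            row += " ".join(f"{int(round(v)):>3}" for v in scores[i])
            row += "  " + " ".join(f"{int(round(v * 100)):>3}" for v in freqs[i])
            row += "  0.00 0.00\n"
            fh.write(row)
        fh.write("\n")
        fh.write("                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1350     0.3180\n")


def read_disorder_tsv(path: str | Path, protein_id: str | None = None) -> DisorderProfile:
    """Parse a disorder table TSV: residue_index, residue, score in [0, 1]."""
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    scores: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ProfileParseError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            idx_s, _residue, score_s = parts
            if lineno == 1 and not idx_s.isdigit():
                continue  # header
            if int(idx_s) != len(scores) + 1:
                raise ProfileParseError(
                    f"{path}:{lineno}: residue index {idx_s} out of order"
                )
            scores.append(float(score_s))
    if not scores:
        raise ProfileParseError(f"{path}: no disorder rows")
    return DisorderProfile(protein_id=protein_id, scores=np.asarray(scores, dtype=float))


def write_disorder_tsv(profile: DisorderProfile, path: str | Path,
                       sequence: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("residue_index\tresidue\tscore\n")
        for i, score in enumerate(profile.scores):
            residue = sequence[i] if sequence else "X"
            fh.write(f"{i + 1}\t{residue}\t{score:.6f}\n")


def _window_row_indices(profile_len: int, window: PeptideWindow) -> list[int | None]:
    """0-based profile row per window position; None for padded positions."""
    r = window.radius
    start = window.center_position - 1 - r
    rows: list[int | None] = []
    for offset in range(2 * r + 1):
        pos = start + offset
        if offset < window.n_pad_left or offset >= 2 * r + 1 - window.n_pad_right:
            rows.append(None)
        elif not 0 <= pos < profile_len:
            raise ValueError(
                f"window at {window.protein_id}:{window.center_position} extends to "
                f"residue {pos + 1} beyond profile of length {profile_len}"
            )
        else:
            rows.append(pos)
    return rows


def slice_pssm(profile: PSSMProfile, window: PeptideWindow) -> np.ndarray:
    """Window-local (2r+1)×20 score matrix; padded positions are zero rows."""
    if profile.protein_id != window.protein_id:
        raise ValueError(
            f"profile {profile.protein_id!r} does not match window protein "
            f"{window.protein_id!r}"
        )
    rows = _window_row_indices(len(profile), window)
    out = np.zeros((len(rows), 20), dtype=float)
    for i, row in enumerate(rows):
        if row is not None:
            out[i] = profile.scores[row]
    return out


def slice_disorder(profile: DisorderProfile, window: PeptideWindow) -> np.ndarray:
    """Window-local (2r+1) score vector; padded positions score 0.0."""
    if profile.protein_id != window.protein_id:
        raise ValueError(
            f"profile {profile.protein_id!r} does not match window protein "
            f"{window.protein_id!r}"
        )
    rows = _window_row_indices(len(profile), window)
    return np.array([0.0 if r is None else profile.scores[r] for r in rows])
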