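"""Amino-acid physicochemical property tables for the PseAAC encoder.

The sequence-order correlation factors of pseudo amino acid composition are
computed from three per-residue properties — hydrophobicity, hydrophilicity
and side-chain mass — each standardized to zero mean and unit standard
deviation over the 20 standard amino acids (population SD, the convention of
the PseAAC literature). The raw scales ship as packaged data and can be
swapped via :meth:`AAIndexTable.from_tsv`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

from .windows import STANDARD_AA


@dataclass(frozen=True)
class AAIndexTable:
    """Raw and standardized property values, indexed by canonical AA order.

    Attributes hold length-20 arrays aligned to :data:`STANDARD_AA`:
    ``h1_raw``/``h1`` hydrophobicity, ``h2_raw``/``h2`` hydrophilicity,
    ``m_raw``/``m`` side-chain mass; the unsuffixed arrays are standardized.
    """

    h1_raw: np.ndarray
    h2_raw: np.ndarray
    m_raw: np.ndarray
    h1: np.ndarray
    h2: np.ndarray
    m: np.ndarray

    @staticmethod
    def _standardize(x: np.ndarray) -> np.ndarray:
        sd = x.std()  # population SD over the 20 amino acids
        if sd == 0:
            raise ValueError("property column is constant; cannot standardize")
        return (x - x.mean()) / sd

    @classmethod
    def from_raw(cls, h1_raw, h2_raw, m_raw) -> "AAIndexTable":
        h1_raw = np.asarray(h1_raw, dtype=float)
        h2_raw = np.asarray(h2_raw, dtype=float)
        m_raw = np.asarray(m_raw, dtype=float)
        for name, arr in (("h1", h1_raw), ("h2", h2_raw), ("m", m_raw)):
            if arr.shape != (20,):
                raise ValueError(f"{name}: expected 20 values, got {arr.shape}")
        return cls(
            h1_raw=h1_raw, h2_raw=h2_raw, m_raw=m_raw,
            h1=cls._standardize(h1_raw),
            h2=cls._standardize(h2_raw),
            m=cls._standardize(m_raw),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AAIndexTable":
        """Load a property table TSV with columns aa, hydrophobicity,
        hydrophilicity, side_chain_mass ('#' lines are comments)."""
        values: dict[str, tuple[float, float, float]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#") or line.startswith("aa\t"):
                    continue
                aa, h1, h2, m = line.split("\t")
                values[aa] = (float(h1), float(h2), float(m))
        missing = [aa for aa in STANDARD_AA if aa not in values]
        if missing:
            raise ValueError(f"{path}: missing amino acids {missing}")
        rows = [values[aa] for aa in STANDARD_AA]
        arr = np.array(rows, dtype=float)
        return cls.from_raw(arr[:, 0], arr[:, 1], arr[:, 2])


_DEFAULT: AAIndexTable | None = None


def default_table() -> AAIndexTable:
    """The packaged Chou-convention property table (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("succsite").joinpath("data/pseaac_properties.tsv")
        with resources.as_file(ref) as path:
            _DEFAULT = AAIndexTable.from_tsv(path)
    return _DEFAULT
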