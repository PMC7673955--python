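"""Sequence feature encoders and their fusion into one 2501-D vector.

Each 21-mer lysine-centered window is described by four blocks:

========  ====  ==========================================================
block     dims  content
========  ====  ==========================================================
cksaap    2000  composition of k-spaced amino-acid pairs, k = 0..4:
                for every ordered pair (i, j) of standard amino acids the
                fraction N_ij(k) / N_total with N_total = L − k − 1
disorder    21  per-residue intrinsic-disorder scores (quantitative values
                passed through unchanged)
pseaac      40  Type-1 pseudo amino acid composition: 20 composition terms
                plus λ = 20 sequence-order correlation factors over
                standardized hydrophobicity / hydrophilicity / side-chain
                mass, weighted by w = 0.05
pssm       440  row-major flatten of the window-local 21×20 conservation
                score matrix (420) plus its 20 per-column means
========  ====  ==========================================================

Fused in this order the blocks give a 2501-dimensional vector. Non-standard
and pad residues are treated as missing data: they are excluded from CKSAAP
pair counts and PseAAC composition, and correlation terms touching them are
dropped with the divisor reduced accordingly; CKSAAP denominators stay at
L − k − 1 so padding lowers (never inflates) pair fractions.

All encoders are pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .aaindex import AAIndexTable, default_table
from .windows import PeptideWindow, STANDARD_AA

_AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

#: Conventional boundary between ordered (<0.5) and disordered (>0.5)
#: residues. Not applied when encoding — features use the raw scores — but
#: exposed for qualitative calls.
DISORDER_THRESHOLD = 0.5


def is_disordered(score: float, threshold: float = DISORDER_THRESHOLD) -> bool:
    return score > threshold


@dataclass(frozen=True)
class CKSAAPConfig:
    """k-spaced pair composition settings; pairs at gaps k = 0..k_max."""

    k_max: int = 4

    def __post_init__(self) -> None:
        if self.k_max < 0:
            raise ValueError("k_max must be >= 0")

    @property
    def n_features(self) -> int:
        return 400 * (self.k_max + 1)


@dataclass(frozen=True)
class PseAACConfig:
    """Type-1 pseudo amino acid composition settings.

    ``lam`` (λ) is the maximum sequence-order rank; ``w`` weights the
    correlation factors against the composition terms.
    """

    lam: int = 20
    w: float = 0.05
    window_length: int = 21

    def __post_init__(self) -> None:
        if not 1 <= self.lam < self.window_length:
            raise ValueError(
                f"lambda must satisfy 1 <= lambda < window length "
                f"({self.window_length}), got {self.lam}"
            )
        if self.w <= 0:
            raise ValueError("w must be positive")

    @property
    def n_features(self) -> int:
        return 20 + self.lam


@dataclass(frozen=True)
class FeatureBlockLayout:
    """Ordered named blocks of the fused feature vector."""

    blocks: tuple[tuple[str, int], ...] = (
        ("cksaap", 2000),
        ("disorder", 21),
        ("pseaac", 40),
        ("pssm", 440),
    )

    @property
    def total(self) -> int:
        return sum(dim for _, dim in self.blocks)

    @property
    def offsets(self) -> dict[str, int]:
        out, pos = {}, 0
        for name, dim in self.blocks:
            out[name] = pos
            pos += dim
        return out

    def block_of(self, global_index: int) -> tuple[str, int]:
        """(block name, local index) at a global feature offset."""
        if not 0 <= global_index < self.total:
            raise IndexError(global_index)
        pos = 0
        for name, dim in self.blocks:
            if global_index < pos + dim:
                return name, global_index - pos
            pos += dim
        raise AssertionError("unreachable")

    def feature_names(self, r: int = 10, k_max: int = 4, lam: int = 20) -> list[str]:
        """Stable global names ``<block>:<local-index>:<description>``."""
        names: list[str] = []
        for block, dim in self.blocks:
            if block == "cksaap":
                local = 0
                for k in range(k_max + 1):
                    for a in STANDARD_AA:
                        for b in STANDARD_AA:
                            names.append(f"cksaap:{local}:k{k}_{a}x{b}")
                            local += 1
            elif block == "disorder":
                for local, off in enumerate(range(-r, r + 1)):
                    names.append(f"disorder:{local}:pos{off:+d}")
            elif block == "pseaac":
                for local in range(20):
                    names.append(f"pseaac:{local}:comp_{STANDARD_AA[local]}")
                for j in range(1, lam + 1):
                    names.append(f"pseaac:{19 + j}:corr_{j}")
            elif block == "pssm":
                local = 0
                for off in range(-r, r + 1):
                    for a in STANDARD_AA:
                        names.append(f"pssm:{local}:pos{off:+d}_{a}")
                        local += 1
                for a in STANDARD_AA:
                    names.append(f"pssm:{local}:mean_{a}")
                    local += 1
            else:
                names.extend(f"{block}:{i}:" for i in range(dim))
        assert len(names) == self.total
        return names


DEFAULT_LAYOUT = FeatureBlockLayout()


@dataclass(frozen=True)
class FeatureVector:
    """A finite real feature vector tagged with the block it encodes."""

    values: np.ndarray
    block: str
    window: PeptideWindow | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"{self.block}: non-finite feature values")

    def __len__(self) -> int:
        return len(self.values)


def _codes(residues: str) -> np.ndarray:
    """Residue letters -> canonical indices 0..19; -1 for non-standard/pad."""
    return np.array([_AA_INDEX.get(ch, -1) for ch in residues], dtype=np.int64)


def encode_cksaap(window: PeptideWindow,
                  cfg: CKSAAPConfig = CKSAAPConfig()) -> FeatureVector:
    """Composition of k-spaced amino-acid pairs.

    For each gap k, every ordered standard-AA pair (a, b) occurring at
    positions (i, i+k+1) is counted; the 400 counts are divided by
    N_total = L − k − 1. Blocks are ordered k = 0 first; within a block
    pairs run row-major in canonical AA order.
    """
    L = len(window.residues)
    if L < cfg.k_max + 2:
        raise ValueError(f"window of length {L} too short for k_max={cfg.k_max}")
    codes = _codes(window.residues)
    out = np.empty(cfg.n_features, dtype=float)
    for k in range(cfg.k_max + 1):
        a, b = codes[: L - k - 1], codes[k + 1:]
        valid = (a >= 0) & (b >= 0)
        counts = np.bincount(a[valid] * 20 + b[valid], minlength=400)
        out[k * 400:(k + 1) * 400] = counts / (L - k - 1)
    return FeatureVector(out, "cksaap", window)


def encode_disorder(window_scores: np.ndarray,
                    window: PeptideWindow | None = None) -> FeatureVector:
    """Identity pass-through of the 21 window-local disorder scores."""
    scores = np.asarray(window_scores, dtype=float)
    if scores.ndim != 1:
        raise ValueError("disorder scores must be a 1-D vector")
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("disorder scores must lie in [0, 1]")
    return FeatureVector(scores.copy(), "disorder", window)


def encode_pseaac(window: PeptideWindow,
                  table: AAIndexTable | None = None,
                  cfg: PseAACConfig = PseAACConfig()) -> FeatureVector:
    """Type-1 pseudo amino acid composition.

    The first 20 components are the composition fractions f of the standard
    amino acids; the remaining λ components are the weighted sequence-order
    correlation factors b_j, where b_j averages — over all residue pairs
    (i, i+j) with both residues standard — the mean of squared differences
    of the three standardized properties. All 20+λ components share the
    denominator Σf + w·Σb, so the vector sums to 1.
    """
    if table is None:
        table = default_table()
    residues = window.residues
    L = len(residues)
    if cfg.lam >= L:
        raise ValueError(f"lambda={cfg.lam} must be < window length {L}")
    codes = _codes(residues)
    standard = codes >= 0
    if not standard.any():
        raise ValueError(
            f"window at {window.protein_id}:{window.center_position} has no "
            f"standard residues; composition undefined"
        )
    counts = np.bincount(codes[standard], minlength=20).astype(float)
    f = counts / counts.sum()  # composition fractions, sum 1

    # property rows aligned to the window; NaN marks non-standard positions
    props = np.full((3, L), np.nan)
    for p, col in enumerate((table.h1, table.h2, table.m)):
        props[p, standard] = col[codes[standard]]

    b = np.zeros(cfg.lam)
    for j in range(1, cfg.lam + 1):
        diff = props[:, : L - j] - props[:, j:]
        terms = np.mean(diff * diff, axis=0)  # mean over the 3 properties
        valid = ~np.isnan(terms)
        if valid.any():
            b[j - 1] = terms[valid].mean()

    denom = f.sum() + cfg.w * b.sum()
    out = np.concatenate([f / denom, cfg.w * b / denom])
    return FeatureVector(out, "pseaac", window)


def encode_pssm(window_scores: np.ndarray,
                window: PeptideWindow | None = None) -> FeatureVector:
    """Flatten + column means of the window-local conservation matrix.

    The first 420 values are the row-major flatten (position-major: all 20
    scores of position 1, then position 2, ...); the last 20 are per-column
    means over the 21 positions.
    """
    m = np.asarray(window_scores, dtype=float)
    if m.ndim != 2 or m.shape[1] != 20:
        raise ValueError(f"expected a (2r+1)×20 matrix, got {m.shape}")
    return FeatureVector(np.concatenate([m.ravel(), m.mean(axis=0)]), "pssm", window)


def fuse(blocks: dict[str, FeatureVector],
         layout: FeatureBlockLayout = DEFAULT_LAYOUT) -> FeatureVector:
    """Concatenate encoder outputs in layout order into the fused vector."""
    parts = []
    window = None
    for name, dim in layout.blocks:
        if name not in blocks:
            raise ValueError(f"missing feature block {name!r}")
        fv = blocks[name]
        if len(fv) != dim:
            raise ValueError(f"block {name!r} has {len(fv)} values, layout expects {dim}")
        parts.append(fv.values)
        window = window or fv.window
    return FeatureVector(np.concatenate(parts), "fused", window)


def encode_window(window: PeptideWindow,
                  pssm_scores: np.ndarray,
                  disorder_scores: np.ndarray,
                  table: AAIndexTable | None = None,
                  cksaap_cfg: CKSAAPConfig = CKSAAPConfig(),
                  pseaac_cfg: PseAACConfig = PseAACConfig(),
                  layout: FeatureBlockLayout = DEFAULT_LAYOUT) -> FeatureVector:
    """Run all four encoders on one window and fuse the result."""
    return fuse({
        "cksaap": encode_cksaap(window, cksaap_cfg),
        "disorder": encode_disorder(disorder_scores, window),
        "pseaac": encode_pseaac(window, table, pseaac_cfg),
        "pssm": encode_pssm(pssm_scores, window),
    }, layout)


# --------------------------------------------------------------------------
# dataset-level encoding and feature-matrix I/O

def encode_dataset(windows, pssm_profiles, disorder_profiles,
                   table: AAIndexTable | None = None,
                   cksaap_cfg: CKSAAPConfig = CKSAAPConfig(),
                   pseaac_cfg: PseAACConfig = PseAACConfig()) -> pd.DataFrame:
    """Encode a list of windows into a feature DataFrame.

    ``pssm_profiles`` / ``disorder_profiles`` map protein id to profile.
    Columns are the named fused features; a ``label`` column (1/0, or -1
    for unlabeled windows) comes last.
    """
    from .profiles import slice_disorder, slice_pssm

    layout = DEFAULT_LAYOUT
    r = windows[0].radius if windows else 10
    names = layout.feature_names(r=r, k_max=cksaap_cfg.k_max, lam=pseaac_cfg.lam)
    rows = np.empty((len(windows), layout.total), dtype=float)
    labels = np.empty(len(windows), dtype=int)
    for i, w in enumerate(windows):
        pssm = slice_pssm(pssm_profiles[w.protein_id], w)
        dis = slice_disorder(disorder_profiles[w.protein_id], w)
        rows[i] = encode_window(w, pssm, dis, table, cksaap_cfg, pseaac_cfg, layout).values
        labels[i] = {"positive": 1, "negative": 0, None: -1}[w.label]
    df = pd.DataFrame(rows, columns=names)
    df["label"] = labels
    return df


def write_feature_tsv(df: pd.DataFrame, path, sidecar: bool = False) -> None:
    """Write a feature matrix as TSV (label column last); optionally also an
    ``.npz`` binary sidecar next to it for fast reloads."""
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    if sidecar:
        np.savez_compressed(
            str(path) + ".npz",
            values=df.drop(columns=["label"]).to_numpy(),
            label=df["label"].to_numpy(),
            columns=np.array(df.columns[:-1], dtype=object),
        )


def read_feature_tsv(path) -> pd.DataFrame:
    """Read a feature matrix, preferring the ``.npz`` sidecar if present."""
    import os

    npz = str(path) + ".npz"
    if os.path.exists(npz):
        z = np.load(npz, allow_pickle=True)
        df = pd.DataFrame(z["values"], columns=list(z["columns"]))
        df["label"] = z["label"]
        return df
    return pd.read_csv(path, sep="\t")
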