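"""Synthetic labeled datasets with controllable signal.

No public accession exists for the curated succinylation training set, so
every stage of the pipeline is exercised on generated data whose signal is
known by construction. A :class:`SyntheticSpec` plants three kinds of
class-dependent structure:

* **motif enrichment** — positive windows carry specified residues at
  specified offsets from the central lysine with a given probability
  (default: 'E' at offsets ±1 with probability 0.9), so the k-spaced pair
  features for the enriched pairs separate the classes;
* **conservation shift** — PSSM rows at motif positions are shifted in the
  motif residue's column for positive proteins;
* **disorder contrast** — per-residue disorder scores are drawn around
  class-dependent means.

Setting enrichment to zero, the shift to zero and equal means yields a
null dataset on which any classifier should sit at chance. The generator
writes the same three text formats the real pipeline reads (FASTA,
PSI-BLAST ASCII PSSM, disorder TSV) and is byte-reproducible per seed.

Generated proteins are sized so every labeled site is interior to the
sequence (no terminal padding); padding behavior is exercised separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import ConfusionCounts
from .profiles import DisorderProfile, PSSMProfile, write_ascii_pssm, write_disorder_tsv
from .windows import (NEGATIVE, POSITIVE, ProteinRecord, SiteLabel, STANDARD_AA,
                      write_site_table)

#: Swiss-Prot-like amino-acid background frequencies (UniProtKB/Swiss-Prot
#: release statistics, rounded; renormalized at use).
SWISSPROT_FREQS = {
    "A": 0.0826, "R": 0.0553, "N": 0.0406, "D": 0.0546, "C": 0.0137,
    "Q": 0.0393, "E": 0.0672, "G": 0.0708, "H": 0.0227, "I": 0.0591,
    "L": 0.0965, "K": 0.0580, "M": 0.0241, "F": 0.0386, "P": 0.0474,
    "S": 0.0665, "T": 0.0536, "W": 0.0110, "Y": 0.0292, "V": 0.0686,
}


@dataclass(frozen=True)
class MotifRule:
    """Plant ``residue`` at ``offset`` from the center with probability
    ``enrichment`` in positive windows."""

    offset: int
    residue: str
    enrichment: float

    def __post_init__(self) -> None:
        if self.offset == 0:
            raise ValueError("offset 0 is the central lysine itself")
        if self.residue not in STANDARD_AA:
            raise ValueError(f"motif residue must be standard, got {self.residue!r}")
        if not 0.0 <= self.enrichment <= 1.0:
            raise ValueError("enrichment must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one generated dataset."""

    n_positive: int = 500
    n_negative: int = 500
    r: int = 10
    motif: tuple[MotifRule, ...] = (
        MotifRule(-1, "E", 0.9),
        MotifRule(+1, "E", 0.9),
    )
    background: str = "uniform"  # "uniform" | "swissprot"
    pssm_signal_strength: float = 2.0
    disorder_mean_positive: float = 0.65
    disorder_mean_negative: float = 0.35
    disorder_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_positive < 1 or self.n_negative < 1:
            raise ValueError("need at least one sample per class")
        if self.r < 1:
            raise ValueError("window radius must be >= 1")
        for rule in self.motif:
            if abs(rule.offset) > self.r:
                raise ValueError(f"motif offset {rule.offset} outside ±r")
        if self.background not in ("uniform", "swissprot"):
            raise ValueError(f"unknown background {self.background!r}")
        for m in (self.disorder_mean_positive, self.disorder_mean_negative):
            if not 0.0 <= m <= 1.0:
                raise ValueError("disorder class means must lie in [0, 1]")

    @classmethod
    def null(cls, n_positive: int = 500, n_negative: int = 500,
             seed: int = 0, r: int = 10) -> "SyntheticSpec":
        """A zero-signal spec: labels are independent of all features."""
        return cls(
            n_positive=n_positive, n_negative=n_negative, r=r,
            motif=(), pssm_signal_strength=0.0,
            disorder_mean_positive=0.5, disorder_mean_negative=0.5,
            seed=seed,
        )

    def background_probs(self) -> np.ndarray:
        if self.background == "uniform":
            return np.full(20, 1 / 20)
        p = np.array([SWISSPROT_FREQS[aa] for aa in STANDARD_AA])
        return p / p.sum()


@dataclass(frozen=True)
class SyntheticDataset:
    """In-memory dataset plus (optionally) the paths it was written to."""

    proteins: tuple[ProteinRecord, ...]
    sites: tuple[SiteLabel, ...]
    pssm_profiles: dict[str, PSSMProfile]
    disorder_profiles: dict[str, DisorderProfile]
    paths: dict[str, Path] = field(default_factory=dict)


def _write_fasta(proteins, path: Path) -> None:
    with open(path, "w") as fh:
        for p in proteins:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), 60):
                fh.write(p.sequence[i:i + 60] + "\n")


def generate_dataset(spec: SyntheticSpec,
                     outdir: str | Path | None = None) -> SyntheticDataset:
    """Generate one protein per labeled site, with consistent profiles.

    Returns the in-memory dataset; when ``outdir`` is given also writes
    ``proteins.fasta``, ``sites.tsv``, ``pssm/<id>.pssm`` and
    ``disorder/<id>.tsv`` under it.
    """
    rng = np.random.default_rng(spec.seed)
    probs = spec.background_probs()
    aa_arr = np.frombuffer(STANDARD_AA.encode(), dtype="S1").astype("U1")

    proteins: list[ProteinRecord] = []
    sites: list[SiteLabel] = []
    pssms: dict[str, PSSMProfile] = {}
    disorders: dict[str, DisorderProfile] = {}

    labels = [POSITIVE] * spec.n_positive + [NEGATIVE] * spec.n_negative
    for idx, label in enumerate(labels):
        pid = f"SYN{'P' if label == POSITIVE else 'N'}{idx:05d}"
        L = int(rng.integers(2 * spec.r + 25, 2 * spec.r + 41))
        center = int(rng.integers(spec.r + 1, L - spec.r + 1))  # 1-based, interior
        seq = rng.choice(aa_arr, size=L, p=probs)
        seq[center - 1] = "K"
        if label == POSITIVE:
            for rule in spec.motif:
                if rng.random() < rule.enrichment:
                    seq[center - 1 + rule.offset] = rule.residue
        sequence = "".join(seq)

        scores = rng.integers(-5, 6, size=(L, 20)).astype(float)
        if label == POSITIVE and spec.pssm_signal_strength:
            for rule in spec.motif:
                row = center - 1 + rule.offset
                col = STANDARD_AA.index(rule.residue)
                scores[row, col] += spec.pssm_signal_strength
        np.clip(scores, -10, 10, out=scores)
        freqs = rng.integers(0, 9, size=(L, 20)).astype(float) / 100.0

        mean = (spec.disorder_mean_positive if label == POSITIVE
                else spec.disorder_mean_negative)
        dscores = np.clip(rng.normal(mean, spec.disorder_sd, size=L), 0.0, 1.0)

        proteins.append(ProteinRecord(pid, sequence))
        sites.append(SiteLabel(pid, center, label))
        pssms[pid] = PSSMProfile(pid, scores, freqs)
        disorders[pid] = DisorderProfile(pid, dscores)

    paths: dict[str, Path] = {}
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "pssm").mkdir(parents=True, exist_ok=True)
        (outdir / "disorder").mkdir(parents=True, exist_ok=True)
        paths["fasta"] = outdir / "proteins.fasta"
        paths["sites"] = outdir / "sites.tsv"
        paths["pssm_dir"] = outdir / "pssm"
        paths["disorder_dir"] = outdir / "disorder"
        _write_fasta(proteins, paths["fasta"])
        write_site_table(sites, paths["sites"])
        for p in proteins:
            write_ascii_pssm(pssms[p.id], paths["pssm_dir"] / f"{p.id}.pssm",
                             sequence=p.sequence)
            write_disorder_tsv(disorders[p.id],
                               paths["disorder_dir"] / f"{p.id}.tsv",
                               sequence=p.sequence)

    return SyntheticDataset(
        proteins=tuple(proteins), sites=tuple(sites),
        pssm_profiles=pssms, disorder_profiles=disorders, paths=paths,
    )


def encode_synthetic(dataset: SyntheticDataset):
    """Window + encode a generated dataset into a feature DataFrame."""
    from .encoders import encode_dataset
    from .windows import extract_windows

    by_id = {p.id: p for p in dataset.proteins}
    windows = []
    for site in dataset.sites:
        windows.extend(extract_windows(by_id[site.protein_id], [site]))
    return encode_dataset(windows, dataset.pssm_profiles, dataset.disorder_profiles)


def generate_confusion_tables(n: int, seed: int = 0,
                              max_total: int = 200) -> list[ConfusionCounts]:
    """Random non-degenerate confusion tables for metric fuzz tests."""
    rng = np.random.default_rng(seed)
    tables: list[ConfusionCounts] = []
    for _ in range(n):
        total = int(rng.integers(1, max_total + 1))
        probs = rng.dirichlet(np.ones(4))
        tp, fp, tn, fn = rng.multinomial(total, probs)
        tables.append(ConfusionCounts(int(tp), int(fp), int(tn), int(fn)))
    return tables
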