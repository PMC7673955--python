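"""File-level plumbing: encode a dataset from its on-disk artifacts.

Glues the readers to the encoders: FASTA proteins + site table + per-protein
PSSM and disorder files in, a named feature matrix out. Used by the CLI and
handy for scripting.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .aaindex import AAIndexTable
from .encoders import CKSAAPConfig, PseAACConfig, encode_dataset
from .profiles import read_ascii_pssm, read_disorder_tsv
from .windows import extract_windows, read_fasta, read_site_table, scan_all_lysines


def _load_profiles(protein_ids, pssm_dir: Path, disorder_dir: Path):
    pssms, disorders = {}, {}
    for pid in protein_ids:
        pssm_path = pssm_dir / f"{pid}.pssm"
        dis_path = disorder_dir / f"{pid}.tsv"
        if not pssm_path.exists():
            raise FileNotFoundError(f"missing PSSM file: {pssm_path}")
        if not dis_path.exists():
            raise FileNotFoundError(f"missing disorder file: {dis_path}")
        pssms[pid] = read_ascii_pssm(pssm_path, protein_id=pid)
        disorders[pid] = read_disorder_tsv(dis_path, protein_id=pid)
    return pssms, disorders


def build_feature_matrix(fasta: str | Path, sites: str | Path | None,
                         pssm_dir: str | Path, disorder_dir: str | Path,
                         r: int = 10, k_max: int = 4, lam: int = 20,
                         w: float = 0.05,
                         table: AAIndexTable | None = None) -> pd.DataFrame:
    """Encode labeled sites (or, if ``sites`` is None, every lysine) into
    the fused feature matrix with a trailing label column (−1 = unlabeled).

    The returned frame carries window identity in its index as
    ``protein_id:position``.
    """
    proteins = {p.id: p for p in read_fasta(fasta)}
    windows = []
    if sites is not None:
        site_list = read_site_table(sites)
        for site in site_list:
            if site.protein_id not in proteins:
                raise ValueError(f"site references unknown protein {site.protein_id!r}")
            windows.extend(extract_windows(proteins[site.protein_id], [site], r=r))
    else:
        for p in proteins.values():
            windows.extend(scan_all_lysines(p, r=r))
    if not windows:
        raise ValueError("no windows to encode")

    ids = sorted({w.protein_id for w in windows})
    pssms, disorders = _load_profiles(ids, Path(pssm_dir), Path(disorder_dir))
    df = encode_dataset(
        windows, pssms, disorders, table=table,
        cksaap_cfg=CKSAAPConfig(k_max=k_max),
        pseaac_cfg=PseAACConfig(lam=lam, w=w, window_length=2 * r + 1),
    )
    df.index = [f"{w.protein_id}:{w.center_position}" for w in windows]
    return df
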