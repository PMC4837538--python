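"""PLINK 1.9 PED/MAP and BED/BIM/FAM readers and writers, plus table I/O.

Dosages count the A1 allele (written as the panel's alt allele); missing
calls round-trip through the PLINK missing codes ("0 0" in PED, code 01 in
BED). Only autosome codes 1-18 are accepted, matching a pig SNP panel.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .popsim import MISSING, GenotypePanel, Pedigree

BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major PLINK BED header
MAX_CHROM = 18

# 2-bit BED codes -> dosage of A1: 00 hom A1 (2), 01 missing, 10 het, 11 hom A2
_BED_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_BED = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


def _check_chroms(chroms) -> None:
    bad = set(int(c) for c in chroms) - set(range(1, MAX_CHROM + 1))
    if bad:
        raise ValueError(f"unsupported chromosome codes {sorted(bad)}; expected autosomes 1-{MAX_CHROM}")


def write_map(marker_map: pd.DataFrame, path: str | Path) -> None:
    _check_chroms(marker_map["chrom"])
    out = pd.DataFrame(
        {
            "chrom": marker_map["chrom"],
            "snp_id": marker_map["snp_id"],
            "cM": marker_map["pos_bp"] / 1e6,  # 1 Mb = 1 cM convention
            "pos_bp": marker_map["pos_bp"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=r"\s+", header=None, names=["chrom", "snp_id", "cM", "pos_bp"]
    )
    _check_chroms(df["chrom"])
    return pd.DataFrame(
        {
            "snp_id": df["snp_id"].astype(str),
            "chrom": df["chrom"].astype(int),
            "pos_bp": df["pos_bp"].astype(np.int64),
            "ref": "A",
            "alt": "B",
        }
    )


def write_ped_map(panel: GenotypePanel, prefix: str | Path) -> None:
    prefix = Path(prefix)
    write_map(panel.marker_map, prefix.with_suffix(".map"))
    a1 = panel.marker_map["alt"].to_numpy()
    a2 = panel.marker_map["ref"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, aid in enumerate(panel.animal_ids):
            alleles = []
            for j, d in enumerate(panel.dosage[i]):
                if d == MISSING:
                    alleles += ["0", "0"]
                elif d == 2:
                    alleles += [a1[j], a1[j]]
                elif d == 1:
                    alleles += [a1[j], a2[j]]
                else:
                    alleles += [a2[j], a2[j]]
            fh.write(" ".join(["FAM1", aid, "0", "0", "0", "-9"] + alleles) + "\n")


def read_ped_map(prefix: str | Path) -> GenotypePanel:
    prefix = Path(prefix)
    mmap = read_map(prefix.with_suffix(".map"))
    ids, rows = [], []
    a1 = mmap["alt"].to_numpy()
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) != 6 + 2 * len(mmap):
                raise ValueError(".ped column count does not match .map")
            ids.append(parts[1])
            al = np.array(parts[6:]).reshape(-1, 2)
            miss = (al == "0").any(axis=1)
            dos = (al == a1[:, None]).sum(axis=1).astype(np.int8)
            dos[miss] = MISSING
            rows.append(dos)
    return GenotypePanel(ids, mmap, np.vstack(rows))


def write_bed(panel: GenotypePanel, prefix: str | Path) -> None:
    """BED/BIM/FAM triple (SNP-major BED with the 0x6c 0x1b 0x01 magic)."""
    prefix = Path(prefix)
    _check_chroms(panel.marker_map["chrom"])
    bim = pd.DataFrame(
        {
            "chrom": panel.marker_map["chrom"],
            "snp_id": panel.marker_map["snp_id"],
            "cM": panel.marker_map["pos_bp"] / 1e6,
            "pos_bp": panel.marker_map["pos_bp"],
            "A1": panel.marker_map["alt"],
            "A2": panel.marker_map["ref"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fam": "FAM1",
            "id": panel.animal_ids,
            "sire": "0",
            "dam": "0",
            "sex": 0,
            "phe": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep=" ", header=False, index=False)
    n = panel.n_animals
    codes = np.empty_like(panel.dosage, dtype=np.uint8)
    for d, c in _DOSAGE_TO_BED.items():
        codes[panel.dosage == d] = c
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(BED_MAGIC)
        buf = np.zeros((panel.n_snps, n_bytes), dtype=np.uint8)
        for k in range(4):
            idx = np.arange(k, n, 4)
            buf[:, (idx // 4)] |= codes[idx, :].T << (2 * k)
        fh.write(buf.tobytes())


def read_bed(prefix: str | Path) -> GenotypePanel:
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cM", "pos_bp", "A1", "A2"],
    )
    _check_chroms(bim["chrom"])
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fam", "id", "sire", "dam", "sex", "phe"],
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != BED_MAGIC:
        raise ValueError(f"{prefix.with_suffix('.bed')}: bad BED magic bytes")
    n_bytes = (n + 3) // 4
    payload = np.frombuffer(raw[3:], dtype=np.uint8)
    if len(payload) != m * n_bytes:
        raise ValueError(
            f"{prefix.with_suffix('.bed')}: payload size does not match .bim/.fam dimensions"
        )
    payload = payload.reshape(m, n_bytes)
    dosage = np.empty((n, m), dtype=np.int8)
    for k in range(4):
        idx = np.arange(k, n, 4)
        codes = (payload[:, idx // 4] >> (2 * k)) & 0b11
        dosage[idx, :] = _BED_TO_DOSAGE[codes].T
    mmap = pd.DataFrame(
        {
            "snp_id": bim["snp_id"].astype(str),
            "chrom": bim["chrom"].astype(int),
            "pos_bp": bim["pos_bp"].astype(np.int64),
            "ref": bim["A2"].astype(str),
            "alt": bim["A1"].astype(str),
        }
    )
    return GenotypePanel(list(fam["id"].astype(str)), mmap, dosage)


def write_pedigree_csv(pedigree: Pedigree, path: str | Path) -> None:
    pedigree.table.to_csv(path, index=False)


def read_pedigree_csv(path: str | Path) -> Pedigree:
    ped = Pedigree(pd.read_csv(path, dtype={"id": str, "sire": str, "dam": str}))
    ped.validate()
    return ped
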