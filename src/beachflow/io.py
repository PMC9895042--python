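"""Readers and writers for the package's plain-text interchange formats.

* VCF v4.2 (diploid GT, one contig per GBS tag, POS = offset + 1) for
  genotype matrices;
* TSV tables for the SNP->tag map, individual site labels, and per-specimen
  luminance values;
* TPS files ("LM=", coordinate lines, "ID=", optional "SCALE=") for landmark
  configurations;
* fastsimcoal-style joint observed-SFS files ("1 observations", "d0_i"
  column and "d1_j" row labels, monomorphic count in cell (0, 0)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simdata import MISSING, GenotypeMatrix, TagMap
from .genomatrix import JointFoldedSFS

__all__ = [
    "write_vcf", "read_vcf", "write_tagmap", "read_tagmap",
    "write_labels", "read_labels", "write_tps", "read_tps",
    "write_obs_sfs", "read_obs_sfs",
]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: GenotypeMatrix, tags: TagMap, path):
    """Write diploid genotypes as VCF v4.2, one contig per tag."""
    tag_of = dict(zip(tags.table["snp_id"], tags.table["tag_id"]))
    off_of = dict(zip(tags.table["snp_id"], tags.table["offset"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=beachflow\n")
        for tag in tags.tag_ids:
            fh.write(f"##contig=<ID={tag},length={tags.contig_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = "\t".join(matrix.samples["individual"])
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{cols}\n")
        for j, sid in enumerate(matrix.snp_ids):
            gt = "\t".join(_GT[int(c)] for c in matrix.codes[:, j])
            fh.write(f"{tag_of[sid]}\t{off_of[sid] + 1}\t{sid}\tA\tT\t.\t"
                     f"PASS\t.\tGT\t{gt}\n")


def read_vcf(path, labels: pd.DataFrame | None = None):
    """Read a diploid VCF into (GenotypeMatrix, TagMap).

    Sample site labels come from ``labels`` (columns individual, locality,
    habitat) when given, else default placeholders.  Only the GT field is
    used; half-calls and multi-allelic records are rejected.
    """
    snp_ids = []
    rows = []
    codes_cols = []
    individuals = None
    contig_len = 300
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##"):
                if line.startswith("##contig=") and "length=" in line:
                    contig_len = int(line.split("length=")[1].rstrip(">"))
                continue
            if line.startswith("#CHROM"):
                individuals = line.split("\t")[9:]
                continue
            f = line.split("\t")
            if "," in f[4]:
                raise ValueError(f"multi-allelic record at {f[0]}:{f[1]}")
            sid = f[2] if f[2] != "." else f"{f[0]}_{f[1]}"
            snp_ids.append(sid)
            rows.append((sid, f[0], int(f[1]) - 1))
            col = []
            fmt = f[8].split(":")
            gi = fmt.index("GT")
            for cell in f[9:]:
                gt = cell.split(":")[gi].replace("|", "/")
                if gt in ("./.", "."):
                    col.append(MISSING)
                else:
                    a, b = gt.split("/")
                    col.append(int(a) + int(b))
            codes_cols.append(col)
    if individuals is None:
        raise ValueError("missing #CHROM header line")
    codes = (np.array(codes_cols, dtype=np.int8).T if codes_cols
             else np.zeros((len(individuals), 0), dtype=np.int8))
    if labels is None:
        samples = pd.DataFrame({"individual": individuals,
                                "locality": 1, "habitat": "B"})
    else:
        samples = labels.set_index("individual").loc[individuals].reset_index()
    tag_table = pd.DataFrame(rows, columns=["snp_id", "tag_id", "offset"])
    return (GenotypeMatrix(codes, samples, snp_ids),
            TagMap(tag_table, contig_length=contig_len))


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_tagmap(tags: TagMap, path):
    tags.table.to_csv(path, sep="\t", index=False)


def read_tagmap(path, contig_length=300):
    return TagMap(pd.read_csv(path, sep="\t"), contig_length=contig_length)


def write_labels(samples: pd.DataFrame, path):
    samples[["individual", "locality", "habitat"]].to_csv(
        path, sep="\t", index=False)


def read_labels(path):
    df = pd.read_csv(path, sep="\t")
    need = {"individual", "locality", "habitat"}
    if not need.issubset(df.columns):
        raise ValueError(f"labels TSV needs columns {sorted(need)}")
    return df


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------

def write_tps(coords: np.ndarray, ids, path, scale=None):
    """Write (n, k, 2) landmark configurations as a TPS file."""
    coords = np.asarray(coords, float)
    with open(path, "w") as fh:
        for i, cid in enumerate(ids):
            fh.write(f"LM={coords.shape[1]}\n")
            for x, y in coords[i]:
                fh.write(f"{x:.6f} {y:.6f}\n")
            if scale is not None:
                fh.write(f"SCALE={scale:.6f}\n")
            fh.write(f"ID={cid}\n")


def read_tps(path):
    """Read a TPS file; returns (coords (n, k, 2), ids, scales)."""
    configs, ids, scales = [], [], []
    cur, k = [], None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            up = line.upper()
            if up.startswith("LM="):
                k = int(line.split("=")[1])
                cur = []
            elif up.startswith("ID="):
                ids.append(line.split("=", 1)[1])
                if len(cur) != k:
                    raise ValueError(f"expected {k} landmarks, got {len(cur)}")
                configs.append(cur)
                if len(scales) < len(configs):
                    scales.append(1.0)
            elif up.startswith("SCALE="):
                scales.append(float(line.split("=")[1]))
            else:
                x, y = line.split()
                cur.append((float(x), float(y)))
    if len({len(c) for c in configs}) > 1:
        raise ValueError("inconsistent landmark counts across specimens")
    return np.array(configs, float), ids, scales


# ---------------------------------------------------------------------------
# observed-SFS files
# ---------------------------------------------------------------------------

def write_obs_sfs(sfs: JointFoldedSFS, path):
    """fastsimcoal-style joint observed SFS (monomorphic count in (0, 0))."""
    counts = sfs.counts.copy()
    counts[0, 0] += sfs.n_monomorphic
    with open(path, "w") as fh:
        fh.write("1 observations\n")
        fh.write("\t" + "\t".join(f"d0_{j}" for j in
                                  range(counts.shape[1])) + "\n")
        for i in range(counts.shape[0]):
            row = "\t".join(f"{counts[i, j]:g}" for j in range(counts.shape[1]))
            fh.write(f"d1_{i}\t{row}\n")


def read_obs_sfs(path) -> JointFoldedSFS:
    with open(path) as fh:
        header = fh.readline()
        if "observations" not in header:
            raise ValueError("not an observed-SFS file")
        fh.readline()  # column labels
        rows = [list(map(float, line.split()[1:])) for line in fh if line.strip()]
    counts = np.array(rows)
    mono = int(counts[0, 0])
    counts[0, 0] = 0.0
    n1 = (counts.shape[0] - 1) // 2
    n2 = (counts.shape[1] - 1) // 2
    return JointFoldedSFS(counts, n1, n2, n_monomorphic=mono)
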