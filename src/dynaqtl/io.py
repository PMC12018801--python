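"""File formats: tabular readers and writers with strict dialects.

Every writer/reader pair round-trips byte-identically (fixed column order,
``%.10g`` float formatting).  Conventions: physical positions are 1-based;
the gene-model file must declare its coordinate convention in a header
comment and 0-based declarations are rejected; the minimal VCF dialect is
biallelic-only.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .haplotypes import HaplotypeProbabilities
from .simulate import FluorescenceTrace

__all__ = [
    "write_map", "read_map",
    "write_genotypes", "read_genotypes",
    "write_vcf", "read_vcf",
    "write_traces", "read_traces",
    "write_phenotypes", "read_phenotypes",
    "write_counts", "read_counts",
    "write_genes", "read_genes",
    "write_probabilities", "read_probabilities",
    "write_viterbi_bed",
]

FLOAT_FMT = "%.10g"
GENE_HEADER = "#coordinates=1-based inclusive"
PROBS_HEADER = "#dynaqtl-probs v1"


# --- genetic map -----------------------------------------------------------

def write_map(gmap: GeneticMap, path: str | Path) -> None:
    gmap.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_map(path: str | Path) -> GeneticMap:
    t = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    expected = ["chrom", "marker", "bp", "cM"]
    if list(t.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, found {list(t.columns)}")
    return GeneticMap(t)


# --- genotype matrices -----------------------------------------------------

def write_genotypes(ids: list[str], alleles: np.ndarray, marker_ids, path: str | Path) -> None:
    """Individuals × markers matrix, codes 0/1 and NA for missing."""
    df = pd.DataFrame(alleles, index=pd.Index(ids, name="id"), columns=list(marker_ids))
    df = df.astype("object").where(df != -1, other=pd.NA)
    df.to_csv(path, sep="\t", na_rep="NA")


def read_genotypes(path: str | Path) -> tuple[list[str], np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    bad = ~df.isin([0, 1]) & df.notna()
    if bad.to_numpy().any():
        raise ValueError(f"{path}: genotype codes must be 0/1/NA")
    alleles = df.fillna(-1).to_numpy(dtype=np.int8)
    return list(df.index), alleles, list(df.columns)


# --- minimal VCF -----------------------------------------------------------

def write_vcf(ids: list[str], alleles: np.ndarray, gmap: GeneticMap, path: str | Path) -> None:
    """Minimal biallelic VCF: one record per marker, inbred diploid GTs."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=dynaqtl",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids),
    ]
    gt_code = {0: "0/0", 1: "1/1", -1: "./."}
    t = gmap.table
    for m in range(len(t)):
        row = t.iloc[m]
        gts = "\t".join(gt_code[int(a)] for a in alleles[:, m])
        lines.append(
            f"{row['chrom']}\t{row['bp']}\t{row['marker']}\tA\tT\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> tuple[list[str], np.ndarray, pd.DataFrame]:
    """Read the minimal dialect; multiallelic records are rejected."""
    ids: list[str] = []
    rows = []
    genos = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if line.startswith("##") or not line.strip():
            continue
        if line.startswith("#CHROM"):
            ids = line.rstrip("\n").split("\t")[9:]
            continue
        parts = line.rstrip("\n").split("\t")
        chrom, pos, mid, _ref, alt = parts[0], parts[1], parts[2], parts[3], parts[4]
        if "," in alt:
            raise ValueError(f"{path}:{lineno}: multiallelic record at {chrom}:{pos} (biallelic-only dialect)")
        calls = []
        for gt in parts[9:]:
            g = gt.split(":")[0].replace("|", "/")
            if g in ("0/0", "0"):
                calls.append(0)
            elif g in ("1/1", "1"):
                calls.append(1)
            elif g in ("./.", "."):
                calls.append(-1)
            else:
                calls.append(2)  # heterozygous: uninformative for inbred lines
        rows.append((chrom, mid, int(pos)))
        genos.append(calls)
    if not ids:
        raise ValueError(f"{path}: missing #CHROM header line")
    meta = pd.DataFrame(rows, columns=["chrom", "marker", "bp"])
    return ids, np.asarray(genos, dtype=np.int8).T, meta


# --- fluorescence traces ---------------------------------------------------

def write_traces(traces: list[FluorescenceTrace], path: str | Path) -> None:
    """Trace CSV: phase ``dark0`` carries (Fo, Fm); light/dark carry (F', Fm')."""
    rows = []
    for tr in traces:
        rows.append((tr.sample_id, "dark0", 0.0, tr.fo, tr.fm))
        for t, fp, fmp in tr.light_pulses:
            rows.append((tr.sample_id, "light", t, fp, fmp))
        for t, fp, fmp in tr.dark_pulses:
            rows.append((tr.sample_id, "dark", t, fp, fmp))
    pd.DataFrame(rows, columns=["sample_id", "phase", "t_s", "F", "Fm_prime"]).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_traces(path: str | Path) -> list[FluorescenceTrace]:
    df = pd.read_csv(path)
    expected = ["sample_id", "phase", "t_s", "F", "Fm_prime"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected columns {expected}, found {list(df.columns)}")
    bad_phase = ~df["phase"].isin(["dark0", "light", "dark"])
    if bad_phase.any():
        raise ValueError(f"{path}: unknown phase values {sorted(df.loc[bad_phase, 'phase'].unique())}")
    traces = []
    for sid, sub in df.groupby("sample_id", sort=False):
        d0 = sub[sub["phase"] == "dark0"]
        if len(d0) != 1:
            raise ValueError(f"{path}: sample {sid} needs exactly one dark0 row")
        light = [tuple(r) for r in sub.loc[sub["phase"] == "light", ["t_s", "F", "Fm_prime"]].to_numpy()]
        dark = [tuple(r) for r in sub.loc[sub["phase"] == "dark", ["t_s", "F", "Fm_prime"]].to_numpy()]
        traces.append(
            FluorescenceTrace(str(sid), float(d0["F"].iloc[0]), float(d0["Fm_prime"].iloc[0]), light, dark)
        )
    return traces


# --- phenotypes, counts, genes --------------------------------------------

PHENO_COLUMNS = ["genotype", "year", "rep", "block", "date", "silking_interval", "trait", "value"]


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.loc[:, PHENO_COLUMNS].to_csv(path, index=False, float_format=FLOAT_FMT)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={c: str for c in PHENO_COLUMNS[:-1]})
    if list(df.columns) != PHENO_COLUMNS:
        raise ValueError(f"{path}: expected columns {PHENO_COLUMNS}, found {list(df.columns)}")
    df["value"] = df["value"].astype(float)
    return df


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")


def read_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any() or not np.allclose(df.to_numpy() % 1, 0):
        raise ValueError(f"{path}: counts must be non-negative integers")
    return df.astype(np.int64)


def write_genes(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(GENE_HEADER + "\n")
        genes.loc[:, ["chrom", "start", "end", "gene_id"]].to_csv(fh, sep="\t", index=False)


def read_genes(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#coordinates="):
            raise ValueError(f"{path}: missing coordinate-convention declaration header")
        if "0-based" in first:
            raise ValueError(f"{path}: 0-based BED-style coordinates offered where 1-based expected")
        if first != GENE_HEADER:
            raise ValueError(f"{path}: unknown coordinate declaration {first!r}")
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    if list(df.columns) != ["chrom", "start", "end", "gene_id"]:
        raise ValueError(f"{path}: expected columns chrom,start,end,gene_id")
    return df


# --- haplotype probabilities ----------------------------------------------

def write_probabilities(probs: HaplotypeProbabilities, path: str | Path) -> None:
    """Wide TSV (ril, marker, one column per founder) with a versioned header."""
    with open(path, "w") as fh:
        fh.write(PROBS_HEADER + "\n")
        probs.to_wide_frame().to_csv(fh, sep="\t", index=False, float_format="%.8g")


def read_probabilities(path: str | Path, gmap: GeneticMap) -> HaplotypeProbabilities:
    with open(path) as fh:
        first = fh.readline().strip()
        if first != PROBS_HEADER:
            raise ValueError(f"{path}: not a dynaqtl probabilities file (header {first!r})")
        df = pd.read_csv(fh, sep="\t")
    founders = [c for c in df.columns if c not in ("ril", "marker")]
    rils = list(dict.fromkeys(df["ril"]))
    m = gmap.n_markers
    arr = df[founders].to_numpy(dtype=float).reshape(len(rils), m, len(founders))
    return HaplotypeProbabilities(arr, rils, founders, gmap)


def write_viterbi_bed(probs: HaplotypeProbabilities, path: str | Path) -> None:
    """Most-probable founder mosaic as (chrom, start_bp, end_bp, founder) rows."""
    if probs.viterbi is None:
        raise ValueError("probabilities carry no Viterbi path; reconstruct with compute_viterbi=True")
    rows = []
    t = probs.gmap.table
    for r, rid in enumerate(probs.ril_ids):
        for c in probs.gmap.chromosomes:
            idx = probs.gmap.marker_indices(c)
            path_c = probs.viterbi[r, idx]
            bp = t["bp"].to_numpy()[idx]
            seg_start = bp[0]
            for j in range(1, len(idx) + 1):
                if j == len(idx) or path_c[j] != path_c[j - 1]:
                    rows.append((rid, c, int(seg_start), int(bp[j - 1]), probs.founder_ids[path_c[j - 1]]))
                    if j < len(idx):
                        seg_start = bp[j]
    pd.DataFrame(rows, columns=["ril", "chrom", "start_bp", "end_bp", "founder"]).to_csv(
        path, sep="\t", index=False
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, default=str) + "\n")
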