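"""Readers and writers for the pipeline's on-disk formats.

VCF (phased GT, optional PL), BEAGLE-style genotype-likelihood text,
truth-tract BED, genetic-map TSV, metadata TSV and chloroplast TSV.
Coordinates are 1-based in VCF on disk and 0-based half-open everywhere in
memory.  All writers are plain text and byte-deterministic.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from hybridswarm.gl_core import GLMatrix
from hybridswarm.simswarm import GeneticMap

VCF_HEADER = """\
##fileformat=VCFv4.2
##source=hybridswarm
##contig=<ID={chrom},length={length}>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(path, individuals, sites: pd.DataFrame, haplotypes: np.ndarray,
              *, contig_length: int | None = None) -> None:
    """Phased diploid VCF; individual i owns haplotype rows 2i, 2i+1."""
    path = Path(path)
    chrom = str(sites["chrom"].iloc[0]) if len(sites) else "1"
    length = contig_length or (int(sites["pos"].max()) + 1 if len(sites) else 1)
    with open(path, "w") as fh:
        fh.write(VCF_HEADER.format(chrom=chrom, length=length))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(individuals) + "\n")
        for m, (c, pos, ref, alt) in enumerate(
                sites[["chrom", "pos", "ref", "alt"]].itertuples(index=False)):
            gts = "\t".join(
                f"{haplotypes[2 * i, m]}|{haplotypes[2 * i + 1, m]}"
                for i in range(len(individuals)))
            fh.write(f"{c}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path):
    """Read a (possibly empty) VCF: returns (individuals, sites, haplotypes).

    Haplotypes are (2n, m) int8 with phase taken from the GT field; in-memory
    positions are 0-based.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows, haps = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"multi-allelic record at {v.CHROM}:{v.POS}")
        rows.append((v.CHROM, v.POS - 1, v.REF, v.ALT[0]))
        pair = np.array([(g[0], g[1]) for g in v.genotypes], dtype=np.int8)
        haps.append(pair.reshape(-1))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    hap = (np.array(haps, dtype=np.int8).T if haps
           else np.zeros((2 * len(individuals), 0), dtype=np.int8))
    return individuals, sites, hap


def write_beagle_gl(path, gl: GLMatrix) -> None:
    """BEAGLE genotype-likelihood text: marker alleleA alleleB + 3 columns
    per individual, linear scale normalized to max 1."""
    lin = gl.linear()
    with open(path, "w") as fh:
        header = ["marker", "allele1", "allele2"]
        for ind in gl.individuals:
            header += [ind] * 3
        fh.write("\t".join(header) + "\n")
        for m, (c, pos) in enumerate(gl.sites[["chrom", "pos"]].itertuples(index=False)):
            vals = "\t".join(f"{lin[i, m, g]:.6g}"
                             for i in range(gl.n_individuals) for g in range(3))
            fh.write(f"{c}_{pos + 1}\t0\t1\t{vals}\n")


def read_beagle_gl(path) -> GLMatrix:
    """Parse BEAGLE GL text back into a GLMatrix (marker ids CHROM_POS1)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        individuals = header[3::3]
        rows, liks = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3 + 3 * len(individuals):
                raise ValueError(f"malformed BEAGLE record at line {lineno}")
            chrom, pos1 = parts[0].rsplit("_", 1)
            rows.append((chrom, int(pos1) - 1, "A", "C"))
            liks.append(np.array(parts[3:], dtype=float).reshape(-1, 3))
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    lin = (np.stack(liks, axis=1) if liks
           else np.zeros((len(individuals), 0, 3)))
    with np.errstate(divide="ignore"):
        ll = np.log(np.maximum(lin, 1e-300))
    return GLMatrix(individuals, sites, ll)


TRACT_COLUMNS = ["chrom", "start", "end", "individual", "label",
                 "start_cm", "end_cm", "length_cm"]


def write_tract_bed(path, tracts: pd.DataFrame) -> None:
    """Tract BED: chrom, start, end, individual, label plus cM columns at
    full precision."""
    df = tracts.copy()
    for col in ("start_cm", "end_cm", "length_cm"):
        df[col] = df[col].map(repr)
    df[TRACT_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_tract_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=TRACT_COLUMNS,
                     dtype={"chrom": str})
    for col in ("start_cm", "end_cm", "length_cm"):
        df[col] = df[col].astype(float)
    return df


def write_genetic_map(path, gmap: GeneticMap) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)


def read_genetic_map(path) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    return GeneticMap(df["pos_bp"].to_numpy(float), df["cm"].to_numpy(float))


def write_metadata(path, metadata: pd.DataFrame) -> None:
    metadata.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_metadata(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_chloroplast(path, individuals, cp_haplotypes: np.ndarray,
                      cp_donor=None) -> None:
    strings = ["".join(map(str, row)) for row in np.asarray(cp_haplotypes, int)]
    df = pd.DataFrame({"individual": individuals, "haplotype": strings})
    if cp_donor is not None:
        df["maternal_donor"] = ["" if d in ("", None) else d for d in cp_donor]
    df.to_csv(path, sep="\t", index=False)


def read_chloroplast(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"haplotype": str})
    if "maternal_donor" in df:
        df["maternal_donor"] = df["maternal_donor"].fillna("")
    return df


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
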