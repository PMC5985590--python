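"""Reading and writing the package's standard file formats.

VCF 4.2 (phased GT for haplotypes, unphased for cohort genotypes, with
the AA INFO tag carrying ancestral alleles), the metadata TSV, and the
truth-record JSON. All emitters stamp the generating seed/config hash
into their headers. Coordinates are 1-based on disk.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import pandas as pd

from .core import MISSING, CohortMetadata, GenotypeMatrix, HaplotypeMatrix


def _config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


# ---------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------
def write_vcf(
    path,
    genotypes: GenotypeMatrix | None = None,
    haplotypes: HaplotypeMatrix | None = None,
    chrom: str = "chr10",
    sample_prefix: str = "hap",
    seed: int | None = None,
) -> None:
    """Write a GenotypeMatrix (unphased) or HaplotypeMatrix (phased).

    Haplotypes are paired two-per-sample (individual-major order) into
    phased diploid GT fields; the ancestral allele goes into the AA tag.
    """
    if (genotypes is None) == (haplotypes is None):
        raise ValueError("provide exactly one of genotypes/haplotypes")
    lines = ["##fileformat=VCFv4.2",
             '##INFO=<ID=AA,Number=1,Type=String,Description='
             '"Ancestral allele">',
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">']
    if seed is not None:
        lines.append(f"##aspenscan_seed={seed}")
    if genotypes is not None:
        G = genotypes
        lines.append(f"##aspenscan_config_hash={_config_hash(G.sites['pos'].tolist())}")
        header = ("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                  + "\t".join(G.individuals))
        lines.append(header)
        aa = G.sites["aa"] if "aa" in G.sites.columns else ["."] * G.n_sites
        code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(G.n_sites):
            row = G.sites.iloc[j]
            gts = "\t".join(code[int(v)] for v in G.dosages[:, j])
            lines.append(
                f"{row['chrom']}\t{row['pos']}\t.\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\tAA={aa[j]}\tGT\t{gts}")
    else:
        H = haplotypes
        if H.n_hap % 2:
            raise ValueError("odd haplotype count cannot form diploids")
        n_ind = H.n_hap // 2
        samples = [f"{sample_prefix}{i:03d}" for i in range(n_ind)]
        lines.append(f"##aspenscan_region_length={H.region_length}")
        lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(samples))
        for j in range(H.n_sites):
            col = H.alleles[:, j]
            gts = "\t".join(
                f"{'.' if col[2*i] == MISSING else col[2*i]}|"
                f"{'.' if col[2*i+1] == MISSING else col[2*i+1]}"
                for i in range(n_ind))
            lines.append(f"{chrom}\t{H.positions[j]}\t.\tA\tC\t.\tPASS\t"
                         f"AA=A\tGT\t{gts}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_metadata(path, meta: CohortMetadata, seed: int | None = None):
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"#aspenscan_seed={seed}\n")
        meta.table.to_csv(fh, sep="\t", index=False)


def write_truth(path, truth: dict) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, default=str)


# ---------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------
def read_vcf(path, as_haplotypes: bool = False):
    """Parse a VCF 4.x into a GenotypeMatrix or HaplotypeMatrix.

    Biallelic SNP records only; multiallelic records are skipped (their
    count is reported in DataFrame.attrs). The AA INFO tag populates
    the ancestral-allele column. Reading haplotypes requires phased GT
    on every record; the first unphased record aborts with its
    coordinates.
    """
    sites = []
    geno_rows = []
    samples = None
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            parts = line.split("\t")
            chrom, pos, _, ref, alt = parts[:5]
            if "," in alt or len(ref) != 1 or len(alt) != 1:
                skipped += 1
                continue
            info = parts[7]
            aa = "."
            for kv in info.split(";"):
                if kv.startswith("AA="):
                    aa = kv[3:]
            gt_idx = parts[8].split(":").index("GT")
            gts = [p.split(":")[gt_idx] for p in parts[9:]]
            if as_haplotypes:
                row = []
                for g in gts:
                    if "|" not in g:
                        raise ValueError(
                            f"unphased genotype {g!r} at {chrom}:{pos}; "
                            "phased GT required for haplotype input")
                    for al in g.split("|"):
                        row.append(MISSING if al == "." else int(al))
            else:
                row = []
                for g in gts:
                    alleles = g.replace("|", "/").split("/")
                    if "." in alleles:
                        row.append(MISSING)
                    else:
                        row.append(sum(int(a) for a in alleles))
            geno_rows.append(row)
            sites.append((chrom, int(pos), ref, alt, aa))
    sites_df = pd.DataFrame(sites,
                            columns=["chrom", "pos", "ref", "alt", "aa"])
    sites_df.attrs["skipped_multiallelic"] = skipped
    data = np.asarray(geno_rows, dtype=np.int8).T
    if as_haplotypes:
        region_length = int(sites_df["pos"].max()) if len(sites_df) else 1
        return HaplotypeMatrix(alleles=data, positions=sites_df["pos"].to_numpy(),
                               region_length=region_length), sites_df
    return GenotypeMatrix(dosages=data, sites=sites_df,
                          individuals=samples or [])


def read_metadata(path) -> CohortMetadata:
    table = pd.read_csv(path, sep="\t", comment="#")
    return CohortMetadata(table=table)
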