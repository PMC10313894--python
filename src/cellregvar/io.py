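"""Readers and writers for the pipeline's file formats.

Conventions: internal coordinates are 0-based half-open; VCF positions
(1-based) are converted at the boundary.  Phenotype BED rows anchor the TSS
at the ``end`` coordinate (start = TSS-1).  All tabular outputs are TSV.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .feature_model import FeatureGrid, FeatureLayout
from .ieqtl import GenotypeMatrix

__all__ = [
    "read_vcf_dosages",
    "write_vcf_dosages",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_phenotype_bed",
    "write_phenotype_bed",
    "read_fraction_tsv",
    "write_fraction_tsv",
    "read_gwas_tsv",
    "write_gwas_tsv",
    "read_feature_store",
    "write_feature_store",
]


def read_vcf_dosages(path: str | Path, region: str | None = None,
                     ) -> GenotypeMatrix:
    """Read a VCF into a dosage matrix; DS preferred over GT when present."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    it = vcf(region) if region else vcf
    for rec in it:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        try:
            ds = rec.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dosage = np.asarray(ds, dtype=float).ravel()[:len(samples)]
        else:
            gts = np.asarray([[g[0], g[1]] for g in rec.genotypes])
            dosage = np.where((gts < 0).any(axis=1), np.nan,
                              (gts > 0).sum(axis=1).astype(float))
        ids.append(vid)
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0] if rec.ALT else ".")
        rows.append(dosage)
    vcf.close()
    dos = pd.DataFrame(np.asarray(rows).T if rows else
                       np.empty((len(samples), 0)),
                       index=samples, columns=ids)
    variants = pd.DataFrame({"chrom": chroms, "pos": poss,
                             "ref": refs, "alt": alts},
                            index=pd.Index(ids, name="variant_id"))
    return GenotypeMatrix(dosages=dos, variants=variants)


def write_vcf_dosages(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write an uncompressed VCF with GT and DS fields from dosages."""
    path = Path(path)
    samples = list(gm.dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Dosage">\n')
        for chrom in pd.unique(gm.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        order = gm.variants.sort_values(["chrom", "pos"]).index
        for vid in order:
            v = gm.variants.loc[vid]
            dos = gm.dosages[vid]
            cells = []
            for d in dos:
                if np.isnan(d):
                    cells.append("./.:.")
                else:
                    n_alt = int(round(d))
                    gt = {0: "0/0", 1: "0/1", 2: "1/1"}.get(n_alt, "./.")
                    cells.append(f"{gt}:{d:g}")
            fh.write(f"{v['chrom']}\t{int(v['pos'])}\t{vid}\t{v.get('ref', 'A')}"
                     f"\t{v.get('alt', 'C')}\t.\t.\t.\tGT:DS\t"
                     + "\t".join(cells) + "\n")


def write_dosage_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    meta = gm.variants[["chrom", "pos"]].copy()
    table = pd.concat([meta, gm.dosages.T], axis=1)
    table.to_csv(path, sep="\t", index_label="variant_id")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    table = pd.read_csv(path, sep="\t", index_col="variant_id")
    variants = table[["chrom", "pos"]]
    dosages = table.drop(columns=["chrom", "pos"]).T
    dosages.columns.name = None
    dosages.index.name = None
    return GenotypeMatrix(dosages=dosages, variants=variants)


def write_phenotype_bed(expr: pd.DataFrame, gene_table: pd.DataFrame,
                        path: str | Path) -> None:
    """Phenotype BED: chrom, start (TSS-1), end (TSS), gene_id, samples.

    Coordinates are 0-based half-open; the TSS is the ``end`` coordinate
    read back as a 1-based position.
    """
    gt = gene_table.set_index("gene_id").loc[expr.index]
    out = pd.DataFrame({
        "#chr": gt["chrom"].to_numpy(),
        "start": gt["tss"].to_numpy() - 1,
        "end": gt["tss"].to_numpy(),
        "gene_id": expr.index,
    })
    out = pd.concat([out.reset_index(drop=True),
                     expr.reset_index(drop=True)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def read_phenotype_bed(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a phenotype BED; returns (gene-by-sample table, gene table).

    Nonstandard rows whose end != start + 1 trigger a warning, not an error.
    """
    import warnings

    table = pd.read_csv(path, sep="\t")
    table = table.rename(columns={table.columns[0]: "chrom"})
    bad = table[table["end"] != table["start"] + 1]
    if len(bad):
        warnings.warn(f"{len(bad)} rows have end != start+1; using end as "
                      "the TSS anyway", stacklevel=2)
    gene_table = pd.DataFrame({
        "gene_id": table["gene_id"], "chrom": table["chrom"],
        "tss": table["end"],
    })
    expr = table.drop(columns=["chrom", "start", "end"]).set_index("gene_id")
    return expr, gene_table


def write_fraction_tsv(fractions: pd.DataFrame, path: str | Path) -> None:
    fractions.to_csv(path, sep="\t", index_label="sample_id")


def read_fraction_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


_GWAS_COLS = ["variant_id", "chrom", "pos", "beta", "se", "p", "N"]


def write_gwas_tsv(stats: pd.DataFrame, path: str | Path) -> None:
    stats[_GWAS_COLS].to_csv(path, sep="\t", index=False)


def read_gwas_tsv(path: str | Path) -> pd.DataFrame:
    stats = pd.read_csv(path, sep="\t")
    missing = set(_GWAS_COLS) - set(stats.columns)
    if missing:
        raise ValueError(f"GWAS summary file lacks columns {sorted(missing)}")
    return stats


def write_feature_store(grids: dict[str, FeatureGrid], path: str | Path,
                        ) -> None:
    """HDF5 store: one float32 dataset per gene plus layout attributes."""
    some = next(iter(grids.values()))
    with h5py.File(path, "w") as h5:
        h5.attrs["window_bp"] = some.layout.window_bp
        h5.attrs["bin_bp"] = some.layout.bin_bp
        h5.attrs["n_features"] = some.layout.n_features
        for gid, grid in grids.items():
            h5.create_dataset(gid, data=grid.values.astype(np.float32))


def read_feature_store(path: str | Path) -> dict[str, FeatureGrid]:
    with h5py.File(path, "r") as h5:
        layout = FeatureLayout(window_bp=int(h5.attrs["window_bp"]),
                               bin_bp=int(h5.attrs["bin_bp"]),
                               n_features=int(h5.attrs["n_features"]))
        return {gid: FeatureGrid(gene_id=gid,
                                 values=np.asarray(h5[gid], dtype=float),
                                 layout=layout)
                for gid in h5.keys()}
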