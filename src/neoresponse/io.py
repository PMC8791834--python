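"""Readers and writers for the pipeline's interchange formats.

Canonical interchange is TSV with a header (gzip transparently supported by
pandas); genomic coordinates are 1-based inclusive throughout.  Mutation
tables can alternatively be read from VCF (via pysam when available), mapping
INFO/FORMAT fields onto the TSV columns.  Every reader validates its schema
and reports the offending file, column and row on violation.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .rnafeat import read_gmt, write_gmt  # re-exported for convenience

__all__ = [
    "read_mutations", "read_mutations_vcf", "read_segments", "read_clinical",
    "read_expression", "read_cells", "read_genome_model", "read_gmt",
    "write_gmt", "write_bundle", "read_bundle", "SchemaError",
    "provenance_manifest",
]


class SchemaError(ValueError):
    """A table failed schema validation; message names file/column/row."""


MUTATION_COLUMNS = {
    "patient": str, "chrom": str, "pos": int, "ref": str, "alt": str,
    "gene": str, "alt_reads": int, "total_reads": int, "cn_normal": int,
    "cn_tumour": int, "purity": float, "context96": int,
}
SEGMENT_COLUMNS = {
    "patient": str, "chrom": str, "start": int, "end": int,
    "major_cn": int, "minor_cn": int,
}
CELL_COLUMNS = {
    "slide_id": str, "cell_id": int, "x": float, "y": float, "cell_class": str,
}


def _read_tsv(path, columns: dict, name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"{name} table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={k: str for k in columns})
    missing = set(columns) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    for col, typ in columns.items():
        try:
            df[col] = df[col].astype(typ)
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: column {col!r} not castable to "
                              f"{typ.__name__}: {exc}") from exc
    return df


def read_mutations(path) -> pd.DataFrame:
    df = _read_tsv(path, MUTATION_COLUMNS, "mutation")
    bad = df.index[df["alt_reads"] > df["total_reads"]]
    if len(bad):
        raise SchemaError(f"{path}: alt_reads > total_reads at row {bad[0] + 2}")
    bad = df.index[(df["purity"] <= 0) | (df["purity"] > 1)]
    if len(bad):
        raise SchemaError(f"{path}: purity outside (0, 1] at row {bad[0] + 2}")
    return df


def read_mutations_vcf(path) -> pd.DataFrame:
    """Read a mutation table from VCF.

    Per-record requirements: INFO fields GENE, CNN (CN_normal), CNT
    (CN_tumour), PURITY and optionally CTX96; one sample with FORMAT fields
    AD (ref,alt depths).  The sample name is taken as the patient identifier.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            for sample in samples:
                call = rec.samples[sample]
                ad = call.get("AD")
                if ad is None or ad[0] is None:
                    continue
                ref_d, alt_d = int(ad[0]), int(ad[1])
                rows.append(
                    {
                        "patient": sample,
                        "chrom": str(rec.chrom),
                        "pos": int(rec.pos),
                        "ref": rec.ref,
                        "alt": rec.alts[0] if rec.alts else ".",
                        "gene": rec.info.get("GENE", "."),
                        "alt_reads": alt_d,
                        "total_reads": ref_d + alt_d,
                        "cn_normal": int(rec.info.get("CNN", 2)),
                        "cn_tumour": int(rec.info.get("CNT", 2)),
                        "purity": float(rec.info.get("PURITY", 1.0)),
                        "context96": int(rec.info.get("CTX96", 0)),
                    }
                )
    return pd.DataFrame(rows, columns=list(MUTATION_COLUMNS))


def read_segments(path) -> pd.DataFrame:
    df = _read_tsv(path, SEGMENT_COLUMNS, "segment")
    bad = df.index[df["start"] > df["end"]]
    if len(bad):
        raise SchemaError(f"{path}: start > end at row {bad[0] + 2}")
    return df


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "patient" not in df.columns:
        raise SchemaError(f"{path}: missing 'patient' column")
    return df.set_index("patient")


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df < 0).any().any():
        raise SchemaError(f"{path}: negative counts")
    return df


def read_gene_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def read_cells(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)  # CSV per the digital-pathology interchange
    missing = set(CELL_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing column(s) {sorted(missing)}")
    return df


def read_genome_model(path) -> pd.DataFrame:
    return _read_tsv(
        path,
        {"chrom": str, "length": int, "centromere_start": int,
         "centromere_end": int},
        "genome model",
    )


# ---------------------------------------------------------------------------
# Bundle round trip
# ---------------------------------------------------------------------------


def write_bundle(bundle, outdir) -> dict[str, Path]:
    """Write a cohort bundle's tables to TSV/CSV/GMT under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    paths["clinical"] = outdir / "clinical.tsv"
    bundle.clinical.reset_index().to_csv(paths["clinical"], sep="\t", index=False)
    paths["mutations"] = outdir / "mutations.tsv"
    bundle.mutations.to_csv(paths["mutations"], sep="\t", index=False)
    paths["segments"] = outdir / "segments.tsv"
    bundle.segments.to_csv(paths["segments"], sep="\t", index=False)
    paths["expression"] = outdir / "expression_counts.tsv"
    bundle.expression.to_csv(paths["expression"], sep="\t")
    paths["gene_lengths"] = outdir / "gene_lengths.tsv"
    bundle.gene_lengths.to_frame().to_csv(paths["gene_lengths"], sep="\t")
    paths["gene_sets"] = outdir / "gene_sets.gmt"
    write_gmt(bundle.gene_sets, paths["gene_sets"])
    paths["immunophenotype"] = outdir / "immunophenotype_groups.gmt"
    write_gmt(bundle.immunophenotype_groups, paths["immunophenotype"])
    paths["cells"] = outdir / "cells.csv"
    bundle.cells.to_csv(paths["cells"], index=False)
    paths["affinities"] = outdir / "affinities.tsv"
    bundle.affinities.to_csv(paths["affinities"], sep="\t", index=False)
    paths["hla"] = outdir / "hla_alleles.tsv"
    bundle.hla.to_csv(paths["hla"], sep="\t", index=False)
    paths["immune_scores"] = outdir / "immune_scores.tsv"
    bundle.immune_scores.reset_index().rename(
        columns={"index": "patient"}
    ).to_csv(paths["immune_scores"], sep="\t", index=False)
    return paths


def read_bundle(indir, config=None):
    """Load a written bundle back into a CohortBundle (ground truth absent)."""
    from .synth import CohortBundle, GroundTruth, SimulationConfig

    indir = Path(indir)
    clinical = read_clinical(indir / "clinical.tsv")
    mutations = read_mutations(indir / "mutations.tsv")
    segments = read_segments(indir / "segments.tsv")
    expression = read_expression(indir / "expression_counts.tsv")
    lengths = read_gene_lengths(indir / "gene_lengths.tsv")
    gene_sets = read_gmt(indir / "gene_sets.gmt")
    groups = read_gmt(indir / "immunophenotype_groups.gmt")
    cells = read_cells(indir / "cells.csv")
    affinities = pd.read_csv(indir / "affinities.tsv", sep="\t")
    hla = pd.read_csv(indir / "hla_alleles.tsv", sep="\t")
    immune = pd.read_csv(indir / "immune_scores.tsv", sep="\t").set_index("patient")
    cfg = config or SimulationConfig(n_patients=len(clinical))
    empty = pd.Series(dtype=float)
    gt = GroundTruth(
        latent=empty, traits=pd.DataFrame(), rcb_class=clinical["rcb_class"],
        true_ccf=empty, signature_weights=pd.DataFrame(),
        lymphocyte_intensity=empty, n_neoantigens=empty,
    )
    return CohortBundle(
        clinical=clinical, mutations=mutations, segments=segments,
        expression=expression, gene_lengths=lengths, gene_sets=gene_sets,
        immunophenotype_groups=groups, cells=cells, affinities=affinities,
        hla=hla, immune_scores=immune, ground_truth=gt, config=cfg,
    )


def provenance_manifest(inputs: dict[str, Path], seed: int, stage: str) -> dict:
    """Checksums + seed + stage, written next to every pipeline artefact."""

    def _sha(p: Path) -> str:
        h = hashlib.sha256()
        with open(p, "rb") as fh:
            for chunk in iter(lambda: fh.read(65536), b""):
                h.update(chunk)
        return h.hexdigest()

    return {
        "stage": stage,
        "seed": int(seed),
        "inputs": {k: {"path": str(p), "sha256": _sha(Path(p))}
                   for k, p in inputs.items() if Path(p).exists()},
    }


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
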