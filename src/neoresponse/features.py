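"""Assembly of the patient x feature predictor matrix.

Runs every feature extractor over a cohort bundle (simulated or loaded from
disk) and assembles the canonical feature matrix: clinical covariates, DNA
features (mutation burden, clonality, neoantigens, HRD, copy-number burden,
driver flags, HLA LOH, signature exposures), RNA scores (proliferation and
immune enrichment, metagenes, hormone-receptor expression, dysfunction and
exclusion inputs), digital-pathology densities and treatment flags.  The
fully integrated configuration is validated against a versioned
feature-definition file (34 features).
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dnafeat, pathfeat, rnafeat
from .synth import CohortBundle

MODALITIES = ("clinical", "DNA", "RNA", "DigPath", "treatment")

CLINICAL_COLUMNS = [
    "age", "tumour_size", "grade", "er_status", "her2_status", "ln_involvement",
]
TREATMENT_COLUMNS = [
    "anthracycline", "anti_her2", "taxane_first", "anthracycline_first",
]


@dataclass
class FeatureMatrix:
    """Patients x named features with modality tags and outcomes."""

    X: pd.DataFrame
    modality: pd.Series  # feature name -> modality tag
    y: pd.Series  # binary pCR
    rcb: pd.Series | None = None

    def subset(self, modalities: list[str]) -> "FeatureMatrix":
        keep = self.modality[self.modality.isin(modalities)].index
        if len(keep) == 0:
            raise ValueError(f"no features for modalities {modalities}")
        return FeatureMatrix(
            X=self.X[keep], modality=self.modality[keep], y=self.y, rcb=self.rcb
        )

    def validate(self, definitions: pd.DataFrame | None = None) -> None:
        """Check the matrix against the feature-definition file: exactly the
        defined names, matching modality tags, unique, no missing values."""
        defs = definitions if definitions is not None else load_feature_definitions()
        expected = list(defs["name"])
        got = list(self.X.columns)
        if sorted(got) != sorted(expected):
            extra = sorted(set(got) - set(expected))
            miss = sorted(set(expected) - set(got))
            raise ValueError(
                f"feature set mismatch: unexpected {extra}, missing {miss}"
            )
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate feature names")
        tags = defs.set_index("name")["modality"]
        for name in got:
            if self.modality[name] != tags[name]:
                raise ValueError(f"modality mismatch for {name}")
        if self.X.isna().any().any():
            bad = list(self.X.columns[self.X.isna().any()])
            raise ValueError(f"missing values in features: {bad}")


def load_feature_definitions() -> pd.DataFrame:
    """The versioned canonical feature list (name, modality, source op)."""
    with resources.files("neoresponse.data").joinpath(
        "feature_definitions.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def dna_features(bundle: CohortBundle) -> pd.DataFrame:
    patients = bundle.clinical.index
    muts = dnafeat.classify_mutations(bundle.mutations)
    out = pd.DataFrame(index=patients)
    counts = muts.groupby("patient").size().reindex(patients, fill_value=0)
    out["tmb"] = [dnafeat.compute_tmb(int(c)) for c in counts]
    by_patient = dict(tuple(muts.groupby("patient")))
    out["pct_subclonal"] = [
        dnafeat.pct_subclonal(by_patient[p]) if p in by_patient else np.nan
        for p in patients
    ]
    retained = dnafeat.filter_neoantigens(bundle.affinities)
    out["n_neoantigens"] = (
        retained.groupby("patient").size().reindex(patients, fill_value=0)
    )
    gm = bundle.config.genome_model
    segs_by_patient = dict(tuple(bundle.segments.groupby("patient")))
    hrd, cna = [], []
    for p in patients:
        segs = segs_by_patient.get(p)
        hrd.append(dnafeat.compute_hrd(segs, gm).total if segs is not None else np.nan)
        cna.append(
            dnafeat.genome_altered_fraction(segs) if segs is not None else np.nan
        )
    out["hrd_score"] = hrd
    out["cna_fraction"] = cna
    flags = dnafeat.driver_flags(bundle.mutations, ["TP53", "PIK3CA"],
                                 patients=list(patients))
    out["tp53_mutated"] = flags["TP53"]
    out["pik3ca_mutated"] = flags["PIK3CA"]
    hla_calls = dnafeat.call_hla_loh(bundle.hla)
    out["hla_loh"] = (
        dnafeat.patient_hla_loh(hla_calls).reindex(patients).fillna(False).astype(int)
    )
    ref = bundle.config.reference_signatures
    sig3, nonclock = [], []
    ctx = bundle.mutations.groupby("patient")["context96"]
    catalogues = {
        p: np.bincount(g.to_numpy(), minlength=96) for p, g in ctx
    }
    for p in patients:
        cat = catalogues.get(p)
        exp = (
            dnafeat.fit_signature_exposures(cat, ref) if cat is not None else None
        )
        if exp is None:
            sig3.append(np.nan)
            nonclock.append(np.nan)
        else:
            ratios, nc = dnafeat.normalize_exposures(exp)
            sig3.append(float(ratios.get("3", np.nan)))
            nonclock.append(nc)
    out["nonclock_fraction"] = nonclock
    out["sig3_exposure"] = sig3
    return out


def rna_features(bundle: CohortBundle, method: str = "ssgsea") -> pd.DataFrame:
    expr = rnafeat.tmm_tpm_normalize(bundle.expression, bundle.gene_lengths)
    sets = bundle.gene_sets
    out = pd.DataFrame(index=expr.tpm.columns)
    out["ggi_score"] = rnafeat.single_sample_score(expr.log_tpm, sets["GGI"], method)
    out["esc_score"] = rnafeat.single_sample_score(
        expr.log_tpm, sets["ESC_MODULE"], method
    )
    out["stat1_score"] = rnafeat.single_sample_score(
        expr.log_tpm, sets["STAT1_MODULE"], method
    )
    out["taxane_metagene"] = rnafeat.taxane_metagene(expr.tpm)
    out["cytolytic_score"] = rnafeat.cytolytic_score(expr.tpm)
    danaher = rnafeat.danaher_scores(
        expr.tpm, {"cd8": sets["DANAHER_CD8"], "mast": sets["DANAHER_MAST"]}
    )
    out["danaher_cd8"] = danaher["cd8"]
    out["danaher_mast"] = danaher["mast"]
    out["t_dysfunction"] = bundle.immune_scores["dysfunction"]
    out["t_exclusion"] = bundle.immune_scores["exclusion"]
    for gene, col in [("ESR1", "esr1_log_tpm"), ("PGR", "pgr_log_tpm"),
                      ("ERBB2", "erbb2_log_tpm")]:
        out[col] = expr.log_tpm.loc[gene]
    return out


def digpath_features(
    bundle: CohortBundle,
    n_neighbours: int = pathfeat.DEFAULT_N,
    max_density_cells: int = 2000,
) -> pd.DataFrame:
    """Slide-level density/fraction features for a whole cohort.

    On slides with very many lymphocytes the median per-cell density is
    computed over a fixed-seed random subsample of ``max_density_cells``
    cells (the kNN distances still use every cell); the Monte-Carlo error of
    the median at that size is negligible next to biological variation.
    """
    cells = bundle.cells
    fractions = pd.crosstab(cells["slide_id"], cells["cell_class"],
                            normalize="index")
    lym = cells[cells["cell_class"] == "lymphocyte"]
    rng = np.random.default_rng(0)
    density = {}
    for slide, grp in lym.groupby("slide_id", sort=False):
        xy = grp[["x", "y"]].to_numpy(float)
        if len(xy) < n_neighbours + 1:
            density[slide] = np.nan
            continue
        if len(xy) > max_density_cells:
            centres = rng.choice(len(xy), max_density_cells, replace=False)
            tree = pathfeat.cKDTree(xy)
            d, _ = tree.query(xy[centres], k=n_neighbours + 1)
            sigma = n_neighbours / (np.pi * d[:, n_neighbours] ** 2)
        else:
            sigma = pathfeat._sigma_from_xy(xy, n_neighbours)
        density[slide] = float(np.median(sigma))
    out = pd.DataFrame(
        {
            "lymphocyte_density": pd.Series(density),
            "lymphocyte_fraction": fractions.get("lymphocyte", 0.0),
        }
    )
    return out.reindex(bundle.clinical.index)


def build_feature_matrix(
    bundle: CohortBundle, enrichment_method: str = "ssgsea"
) -> FeatureMatrix:
    """Full 34-feature matrix with modality tags and outcomes."""
    clin = bundle.clinical
    parts = {
        "clinical": clin[CLINICAL_COLUMNS].astype(float),
        "DNA": dna_features(bundle),
        "RNA": rna_features(bundle, method=enrichment_method),
        "DigPath": digpath_features(bundle),
        "treatment": clin[TREATMENT_COLUMNS].astype(float),
    }
    X = pd.concat(parts.values(), axis=1)
    modality = pd.Series(
        {
            col: tag
            for tag, block in parts.items()
            for col in block.columns
        },
        name="modality",
    )
    return FeatureMatrix(
        X=X,
        modality=modality,
        y=clin["pcr"].astype(int),
        rcb=clin["rcb_class"],
    )
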