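"""Synthetic multi-omic cohort generator with known ground truth.

The generator emulates the joint structure of a neoadjuvant breast-cancer
cohort: clinical covariates, somatic mutation tables with read counts and
copy-number context, allele-specific copy-number segments, an RNA-seq count
matrix with planted proliferation/immune programmes, classified cell tables
from digital pathology, neoepitope candidate affinities, HLA allele copy
numbers, and treatment flags — all tied together by a latent continuous
response.

The generative response model is proportional-odds: each patient carries a
vector of standard-normal latent traits (mutation burden, subclonality, HRD,
copy-number burden, proliferation, immune infiltration, T cell dysfunction and
exclusion, nodal involvement); the latent response is the effect-size-weighted
sum of traits plus unit Gaussian noise; ordered residual-cancer-burden (RCB)
classes are obtained by fixed ascending cutpoints on the latent score, with
scores above the top cutpoint attaining pathological complete response (pCR).
Effect-size signs default to the directions seen in neoadjuvant cohorts:
higher mutation burden, HRD, copy-number alteration, proliferation and immune
infiltration favour pCR; higher subclonality, dysfunction, exclusion and nodal
involvement favour residual disease.

Determinism: one master seed; every table draws from its own substream
``np.random.default_rng([master_seed, OFFSET])`` with fixed per-table offsets
(see ``_STREAMS``), so identical seeds give identical bundles and adding a new
table never perturbs existing ones.
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

RCB_CLASSES = ("pCR", "RCB-I", "RCB-II", "RCB-III")

#: Fixed substream offsets per table (master seed + offset seeds the stream).
_STREAMS = {
    "clinical": 11,
    "mutations": 12,
    "segments": 13,
    "expression": 14,
    "cells": 15,
    "affinities": 16,
    "hla": 17,
    "immune_scores": 18,
    "latent": 19,
}

#: Default effect sizes (log-odds per SD of trait on the latent scale).
#: Signs follow the reported response directions; magnitudes are calibrated
#: so that the planted multi-omic signal jointly dominates the latent
#: response (signal:noise variance ~7:1), the regime the acceptance-level
#: discrimination checks presuppose.
DEFAULT_EFFECT_SIZES = {
    "tmb": 1.1,
    "subclonality": -0.8,
    "hrd": 1.0,
    "cna": 0.7,
    "proliferation": 1.3,
    "immune": 1.1,
    "dysfunction": -0.8,
    "exclusion": -0.5,
    "nodal": -0.5,
}

#: Marginal RCB prior used to place the default cutpoints (worst to best).
DEFAULT_RCB_PRIOR = {"RCB-III": 0.18, "RCB-II": 0.40, "RCB-I": 0.16, "pCR": 0.26}

DEFAULT_SUBTYPE_MIX = {"ER+HER2-": 0.45, "HER2+": 0.30, "TNBC": 0.25}

#: Named marker genes embedded in the synthetic expression matrix.
MITOTIC_GENES = ["BUB1B", "CDK1", "AURKB", "TTK"]
CERAMIDE_GENES = ["UGCG", "CERT1"]
CYTOLYTIC_GENES = ["GZMA", "PRF1"]
HORMONE_GENES = ["ESR1", "PGR", "ERBB2"]
CD8_MARKERS = ["CD8A", "CD8B"]
MAST_MARKERS = ["TPSAB1", "TPSB2", "CPA3", "MS4A2", "HDC"]

TRINUCLEOTIDE_CHANNELS = 96


class ConfigurationError(ValueError):
    """Raised for degenerate simulation configurations."""


def load_genome_model() -> pd.DataFrame:
    """Autosomal genome model (chrom, length, centromere bounds)."""
    with resources.files("neoresponse.data").joinpath(
        "genome_autosomes.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"chrom": str})


def synthetic_reference_signatures(
    n_signatures: int = 5, seed: int = 202_16, sparsity: float = 8.0
) -> pd.DataFrame:
    """Synthetic 96-channel reference signature matrix (columns sum to 1).

    A stand-in for an externally supplied trinucleotide signature catalogue:
    each column is an independent sparse Dirichlet draw with a fixed internal
    seed so the reference is stable across sessions.  Columns are named
    "1", "3", "5", "13", ... with "1" and "5" playing the clock-like roles.
    """
    rng = np.random.default_rng(seed)
    names = ["1", "3", "5", "13", "8", "2", "6", "17"][:n_signatures]
    cols = {}
    for name in names:
        alpha = np.full(TRINUCLEOTIDE_CHANNELS, 1.0 / sparsity)
        col = rng.dirichlet(alpha)
        cols[name] = col / col.sum()
    return pd.DataFrame(cols)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    ``effect_sizes`` maps trait names to signed log-odds per SD on the latent
    response scale; ``rcb_cutpoints`` are three ascending reals partitioning
    the latent score into RCB-III / RCB-II / RCB-I / pCR (low to high); when
    omitted they are placed at the latent quantiles implied by
    ``rcb_prior``.
    """

    n_patients: int = 200
    seed: int = 0
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    rcb_cutpoints: tuple[float, float, float] | None = None
    rcb_prior: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RCB_PRIOR))
    purity_range: tuple[float, float] = (0.3, 0.9)
    depth_mean: float = 160.0
    n_genes: int = 1500
    subtype_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_MIX)
    )
    mean_mutations: float = 90.0
    cn_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.1, 2: 0.6, 3: 0.2, 4: 0.1}
    )
    cell_window: tuple[float, float] = (1000.0, 1000.0)
    base_lymphocyte_intensity: float = 0.003  # cells per px^2
    genome_model: pd.DataFrame = field(default_factory=load_genome_model)
    reference_signatures: pd.DataFrame = field(
        default_factory=synthetic_reference_signatures
    )

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be positive")
        if len(self.genome_model) == 0:
            raise ConfigurationError("genome model is empty")
        if not 0 <= self.purity_range[0] < self.purity_range[1] <= 1:
            raise ConfigurationError("purity_range must be an interval within [0, 1]")
        mix_total = sum(self.subtype_mix.values())
        if abs(mix_total - 1.0) > 1e-8:
            raise ConfigurationError("subtype_mix proportions must sum to 1")
        prior_total = sum(self.rcb_prior.values())
        if abs(prior_total - 1.0) > 1e-8:
            raise ConfigurationError("rcb_prior proportions must sum to 1")
        if all(v == 0 for v in self.effect_sizes.values()) and len(
            self.effect_sizes
        ) == 0:
            raise ConfigurationError("effect_sizes must not be empty")
        if self.rcb_cutpoints is None:
            self.rcb_cutpoints = self._default_cutpoints()
        cp = self.rcb_cutpoints
        if not (cp[0] < cp[1] < cp[2]):
            raise ConfigurationError("rcb_cutpoints must be strictly ascending")
        # expected class occupancy under the cutpoint prior
        probs = self.class_prior()
        if min(self.n_patients * p for p in probs.values()) < 2:
            raise ConfigurationError(
                "n_patients too small: fewer than 2 expected per RCB class"
            )

    def latent_sd(self) -> float:
        """Marginal SD of the latent score (unit noise + weighted traits)."""
        return float(np.sqrt(1.0 + sum(b**2 for b in self.effect_sizes.values())))

    def _default_cutpoints(self) -> tuple[float, float, float]:
        sd = self.latent_sd()
        cum = np.cumsum(
            [self.rcb_prior[c] for c in ("RCB-III", "RCB-II", "RCB-I")]
        )
        return tuple(float(norm.ppf(q) * sd) for q in cum)

    def class_prior(self) -> dict[str, float]:
        """Marginal RCB class probabilities implied by the cutpoints."""
        sd = self.latent_sd()
        c = [x / sd for x in self.rcb_cutpoints]
        return {
            "RCB-III": float(norm.cdf(c[0])),
            "RCB-II": float(norm.cdf(c[1]) - norm.cdf(c[0])),
            "RCB-I": float(norm.cdf(c[2]) - norm.cdf(c[1])),
            "pCR": float(1 - norm.cdf(c[2])),
        }

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


@dataclass
class GroundTruth:
    """Planted parameters recorded alongside the observable tables."""

    latent: pd.Series  # latent response score per patient
    traits: pd.DataFrame  # patients x traits, standard normal
    rcb_class: pd.Series
    true_ccf: pd.Series  # aligned with the mutation table index
    signature_weights: pd.DataFrame  # patients x signatures (simplex rows)
    lymphocyte_intensity: pd.Series  # cells per px^2
    n_neoantigens: pd.Series  # candidates passing all three filters


@dataclass
class CohortBundle:
    """Joint synthetic multi-omic cohort keyed by a shared patient id."""

    clinical: pd.DataFrame
    mutations: pd.DataFrame
    segments: pd.DataFrame
    expression: pd.DataFrame  # genes x patients raw counts
    gene_lengths: pd.Series
    gene_sets: dict[str, list[str]]
    immunophenotype_groups: dict[str, list[str]]
    cells: pd.DataFrame  # slide_id (== patient), cell_id, x, y, cell_class
    affinities: pd.DataFrame
    hla: pd.DataFrame
    immune_scores: pd.DataFrame  # external dysfunction/exclusion inputs
    ground_truth: GroundTruth
    config: SimulationConfig


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Component simulators (unit-testable in isolation)
# ---------------------------------------------------------------------------


def simulate_mutation_reads(
    true_ccf: np.ndarray,
    purity: np.ndarray,
    cn_normal: np.ndarray,
    cn_tumour: np.ndarray,
    depth_mean: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (alt, total, expected VAF) for mutations with known CCF.

    VAF = CCF * p / ((1-p) * CN_normal + p * CN_tumour); total depth is
    Poisson with the given mean (floored at 1) and alt is binomial.  Loci
    with zero tumour copy number are invalid — callers must resample them.
    """
    if np.any(cn_tumour <= 0):
        raise ValueError("CN_tumour must be positive at a mutant locus")
    if np.any((purity <= 0) | (purity > 1)):
        raise ValueError("purity must lie in (0, 1]")
    vaf = true_ccf * purity / ((1 - purity) * cn_normal + purity * cn_tumour)
    if np.any(vaf > 1 + 1e-9):
        raise ValueError("configuration yields VAF > 1")
    total = np.maximum(rng.poisson(depth_mean, size=len(vaf)), 1)
    alt = rng.binomial(total, np.clip(vaf, 0, 1))
    return alt, total, vaf


def simulate_cells(
    intensity: dict[str, float] | float,
    window: tuple[float, float] = (1000.0, 1000.0),
    class_mix: tuple[float, float, float] | None = None,
    rng: np.random.Generator | None = None,
    slide_id: str = "S1",
) -> pd.DataFrame:
    """Homogeneous spatial Poisson process per cell class.

    ``intensity`` is either a {class: cells/px^2} map or a single lymphocyte
    intensity combined with ``class_mix`` proportions over
    (cancer, stromal, lymphocyte).  Counts are Poisson(intensity * area).
    """
    rng = rng or np.random.default_rng(0)
    w, h = window
    area = w * h
    if area <= 0:
        raise ValueError("window area must be positive")
    if isinstance(intensity, dict):
        rates = intensity
    else:
        if class_mix is None:
            raise ValueError("scalar intensity needs class_mix")
        mix = np.asarray(class_mix, dtype=float)
        if mix.sum() <= 0:
            raise ValueError("class_mix must have positive mass")
        mix = mix / mix.sum()
        lym = float(intensity)
        total = lym / mix[2] if mix[2] > 0 else lym
        rates = {
            "cancer": total * mix[0],
            "stromal": total * mix[1],
            "lymphocyte": total * mix[2],
        }
    xs, ys, labels = [], [], []
    for cls in ("cancer", "stromal", "lymphocyte"):
        lam = rates.get(cls, 0.0)
        n = rng.poisson(lam * area)
        xs.append(rng.uniform(0, w, n))
        ys.append(rng.uniform(0, h, n))
        labels.append(np.full(n, cls))
    x = np.concatenate(xs)
    return pd.DataFrame(
        {
            "slide_id": slide_id,
            "cell_id": np.arange(len(x)),
            "x": x,
            "y": np.concatenate(ys),
            "cell_class": np.concatenate(labels),
        }
    )


def simulate_affinities(
    n_candidates: int,
    rng: np.random.Generator,
    patient: str = "P1",
    pass_fraction: float = 0.2,
) -> pd.DataFrame:
    """Neoepitope candidate table with a controlled passing fraction.

    Candidates are marked to pass (mutant < 500 nM, mutant < wild type,
    TPM > 1) with probability ``pass_fraction``; the remainder violate at
    least one filter.  Peptide lengths are drawn from {8, 9, 10, 11} only.
    """
    lengths = rng.choice([8, 9, 10, 11], size=n_candidates)
    passing = rng.random(n_candidates) < pass_fraction
    mutant = np.where(
        passing,
        np.exp(rng.uniform(np.log(5), np.log(450), n_candidates)),
        np.exp(rng.uniform(np.log(600), np.log(30000), n_candidates)),
    )
    wildtype = np.where(
        passing,
        mutant * np.exp(rng.uniform(0.2, 3.0, n_candidates)),
        np.exp(rng.uniform(np.log(50), np.log(30000), n_candidates)),
    )
    tpm = np.where(
        passing,
        np.exp(rng.uniform(np.log(1.5), np.log(200), n_candidates)),
        np.exp(rng.uniform(np.log(0.001), np.log(50), n_candidates)),
    )
    # some non-passers fail only on affinity; some only on expression
    fail_expr = ~passing & (rng.random(n_candidates) < 0.3)
    mutant = np.where(fail_expr, np.exp(rng.uniform(np.log(5), np.log(450),
                                                    n_candidates)), mutant)
    wildtype = np.where(fail_expr, mutant * 2.0, wildtype)
    tpm = np.where(fail_expr, rng.uniform(0.0, 0.9, n_candidates), tpm)
    alleles = rng.choice(["A1", "A2", "B1", "B2", "C1", "C2"], size=n_candidates)
    return pd.DataFrame(
        {
            "patient": patient,
            "peptide": [f"{patient}_pep{i}" for i in range(n_candidates)],
            "length": lengths,
            "mutant_nm": mutant,
            "wildtype_nm": wildtype,
            "allele": alleles,
            "tpm": tpm,
        }
    )


# ---------------------------------------------------------------------------
# Per-table cohort simulators
# ---------------------------------------------------------------------------


def _simulate_latent(cfg: SimulationConfig):
    rng = cfg.rng("latent")
    traits = pd.DataFrame(
        rng.standard_normal((cfg.n_patients, len(cfg.effect_sizes))),
        columns=list(cfg.effect_sizes),
        index=[f"P{i:04d}" for i in range(1, cfg.n_patients + 1)],
    )
    traits.index.name = "patient"
    beta = np.array([cfg.effect_sizes[t] for t in traits.columns])
    latent = traits.to_numpy() @ beta + rng.standard_normal(cfg.n_patients)
    latent = pd.Series(latent, index=traits.index, name="latent")
    c1, c2, c3 = cfg.rcb_cutpoints
    rcb = pd.Series(
        np.select(
            [latent < c1, latent < c2, latent < c3],
            ["RCB-III", "RCB-II", "RCB-I"],
            default="pCR",
        ),
        index=traits.index,
        name="rcb_class",
    )
    return traits, latent, rcb


def _trait(traits: pd.DataFrame, name: str) -> np.ndarray:
    """Trait column, or independent zeros when the trait is not configured."""
    if name in traits.columns:
        return traits[name].to_numpy()
    return np.zeros(len(traits))


def _signal(cfg: SimulationConfig, traits: pd.DataFrame) -> np.ndarray:
    """Standardized effect-weighted trait signal.

    Observables whose response association is not carried by a single trait
    (driver mutations, HLA loss) are driven by this combination, NOT by the
    latent score itself: the latent score contains the response noise, which
    must never leak into observables, or zeroed effect sizes would still
    leave predictive signal.
    """
    beta = np.array([cfg.effect_sizes[t] for t in traits.columns])
    s = traits.to_numpy() @ beta
    sd = float(np.sqrt((beta**2).sum()))
    return s / sd if sd > 0 else np.zeros(len(traits))


def _simulate_clinical(cfg, traits, latent, rcb):
    rng = cfg.rng("clinical")
    n = len(traits)
    idx = traits.index
    subtypes = rng.choice(
        list(cfg.subtype_mix), p=list(cfg.subtype_mix.values()), size=n
    )
    her2 = subtypes == "HER2+"
    prolif = _trait(traits, "proliferation")
    # ER-negative tumours skew proliferative, so ER+ runs against the
    # proliferation trait (and hence against pCR)
    er = rng.random(n) < _sigmoid(0.5 - 0.7 * prolif)
    grade_cuts = np.array([-0.8, 0.4])
    grade = 1 + np.searchsorted(grade_cuts, prolif + 0.3 * rng.standard_normal(n))
    nodal = (_trait(traits, "nodal") + 0.5 * rng.standard_normal(n)) > 0.2
    age = np.round(rng.normal(51, 11, n)).clip(25, 85)
    size = np.round(np.exp(rng.normal(np.log(28), 0.45, n)), 1)
    taxane_first = rng.random(n) < 0.7
    clinical = pd.DataFrame(
        {
            "patient": idx,
            "age": age,
            "tumour_size": size,
            "grade": grade,
            "er_status": er.astype(int),
            "her2_status": her2.astype(int),
            "ln_involvement": nodal.astype(int),
            "chemo_cycles": rng.choice([4, 6, 8], p=[0.2, 0.6, 0.2], size=n),
            "her2_cycles": np.where(her2, rng.choice([2, 3, 4], size=n), 0),
            "anthracycline": (rng.random(n) < 0.87).astype(int),
            "anti_her2": her2.astype(int),
            "taxane_first": taxane_first.astype(int),
            "anthracycline_first": (~taxane_first).astype(int),
            "rcb_class": rcb.to_numpy(),
            "pcr": (rcb == "pCR").astype(int).to_numpy(),
        }
    ).set_index("patient")
    return clinical


def _simulate_mutation_tables(cfg, traits, latent):
    rng = cfg.rng("mutations")
    gm = cfg.genome_model
    ref = cfg.reference_signatures
    idx = traits.index
    n = len(idx)
    signal = _signal(cfg, traits)
    purity = rng.uniform(*cfg.purity_range, size=n)
    n_mut = rng.poisson(
        cfg.mean_mutations * np.exp(0.6 * _trait(traits, "tmb"))
    ).clip(min=5)
    frac_sub = _sigmoid(-1.0 + 1.0 * _trait(traits, "subclonality"))
    p_tp53 = _sigmoid(0.3 + 1.0 * signal)
    p_pik3ca = _sigmoid(-1.0 - 0.7 * signal)

    cn_states = np.array(sorted(cfg.cn_weights))
    cn_probs = np.array([cfg.cn_weights[c] for c in cn_states], dtype=float)
    if (cn_probs < 0).any() or cn_probs.sum() <= 0:
        raise ConfigurationError("cn_weights must be non-negative with positive mass")
    cn_probs = cn_probs / cn_probs.sum()
    valid = cn_states > 0  # CN 0 at a mutant locus is rejected outright
    cn_states, cn_probs = cn_states[valid], cn_probs[valid] / cn_probs[valid].sum()

    # per-patient true signature mixtures over the synthetic reference
    raw = np.column_stack(
        [
            np.full(n, 1.2),  # clock "1"
            0.8 * np.exp(0.8 * _trait(traits, "hrd")),  # HRD-like "3"
            np.full(n, 0.5),  # clock "5"
            0.4 * np.exp(0.3 * _trait(traits, "tmb")),  # APOBEC-like "13"
        ]
    )
    extra = ref.shape[1] - raw.shape[1]
    if extra > 0:
        raw = np.column_stack([raw, np.full((n, extra), 0.15)])
    sig_w = raw[:, : ref.shape[1]]
    sig_w = sig_w / sig_w.sum(axis=1, keepdims=True)
    sig_weights = pd.DataFrame(sig_w, index=idx, columns=ref.columns)

    chrom_lengths = gm.set_index("chrom")["length"]
    bases = np.array(["A", "C", "G", "T"])
    frames = []
    true_ccfs = []
    for i, patient in enumerate(idx):
        m = int(n_mut[i])
        subclonal = rng.random(m) < frac_sub[i]
        ccf = np.where(subclonal, 0.1 + 0.6 * rng.beta(2, 3, m), 1.0)
        cn_t = rng.choice(cn_states, p=cn_probs, size=m)
        cn_n = np.full(m, 2)
        alt, total, _ = simulate_mutation_reads(
            ccf, np.full(m, purity[i]), cn_n, cn_t, cfg.depth_mean, rng
        )
        chroms = rng.choice(chrom_lengths.index, size=m)
        pos = (rng.random(m) * chrom_lengths.loc[chroms].to_numpy()).astype(np.int64) + 1
        channel_probs = ref.to_numpy() @ sig_w[i]
        contexts = rng.choice(TRINUCLEOTIDE_CHANNELS, size=m, p=channel_probs)
        genes = np.char.add(
            "GENE", np.char.zfill(rng.integers(0, 800, size=m).astype(str), 4)
        )
        if rng.random() < p_tp53[i]:
            genes[0] = "TP53"
        if m > 1 and rng.random() < p_pik3ca[i]:
            genes[1] = "PIK3CA"
        refb = rng.integers(0, 4, size=m)
        altb = (refb + rng.integers(1, 4, size=m)) % 4  # always != ref
        frames.append(
            pd.DataFrame(
                {
                    "patient": patient,
                    "chrom": chroms,
                    "pos": pos,
                    "ref": bases[refb],
                    "alt": bases[altb],
                    "gene": genes,
                    "alt_reads": alt.astype(int),
                    "total_reads": total.astype(int),
                    "cn_normal": 2,
                    "cn_tumour": cn_t.astype(int),
                    "purity": float(purity[i]),
                    "context96": contexts.astype(int),
                }
            )
        )
        true_ccfs.append(pd.Series(ccf))
    mutations = pd.concat(frames, ignore_index=True)
    true_ccf = pd.concat(true_ccfs, ignore_index=True)
    true_ccf.index = mutations.index
    return mutations, true_ccf, sig_weights, pd.Series(purity, index=idx)


def _carve(segs: list[list], start: int, end: int, major: int, minor: int):
    """Overwrite [start, end] in a per-chromosome segment list (1-based)."""
    out = []
    for s, e, ma, mi in segs:
        if e < start or s > end:
            out.append([s, e, ma, mi])
            continue
        if s < start:
            out.append([s, start - 1, ma, mi])
        if e > end:
            out.append([end + 1, e, ma, mi])
    out.append([start, end, major, minor])
    return sorted(out)


def _simulate_segments(cfg, traits):
    rng = cfg.rng("segments")
    gm = cfg.genome_model
    MB = 1_000_000
    rows = []
    hrd_rate = np.exp(1.1 * _trait(traits, "hrd"))
    cna_rate = _sigmoid(-1.2 + 1.0 * _trait(traits, "cna"))
    for i, patient in enumerate(traits.index):
        chrom_segs = {
            str(r.chrom): [[1, int(r.length), 1, 1]] for r in gm.itertuples()
        }
        lengths = gm.set_index("chrom")["length"]
        # whole-arm gains driving the copy-number-altered fraction
        for r in gm.itertuples():
            if rng.random() < cna_rate[i]:
                c = str(r.chrom)
                if rng.random() < 0.5:
                    chrom_segs[c] = _carve(
                        chrom_segs[c], 1, int(r.centromere_start) - 1, 2, 1
                    )
                else:
                    chrom_segs[c] = _carve(
                        chrom_segs[c], int(r.centromere_end) + 1, int(r.length), 2, 1
                    )
        # HRD scars: interstitial LOH, telomeric imbalance, LST-style jumps
        n_loh = rng.poisson(1.5 * hrd_rate[i])
        n_tai = rng.poisson(1.5 * hrd_rate[i])
        n_lst = rng.poisson(2.0 * hrd_rate[i])
        for _ in range(n_loh):
            r = gm.iloc[rng.integers(len(gm))]
            span = int(rng.uniform(16, 40) * MB)
            lo = int(rng.uniform(2 * MB, max(r.length - span - 2 * MB, 3 * MB)))
            chrom_segs[str(r.chrom)] = _carve(
                chrom_segs[str(r.chrom)], lo, lo + span, 1 + rng.integers(0, 2), 0
            )
        for _ in range(n_tai):
            r = gm.iloc[rng.integers(len(gm))]
            if rng.random() < 0.5:
                span = int(rng.uniform(5, 30) * MB)
                span = min(span, int(r.centromere_start) - 2)
                chrom_segs[str(r.chrom)] = _carve(
                    chrom_segs[str(r.chrom)], 1, span, 2, 1
                )
            else:
                span = int(rng.uniform(5, 30) * MB)
                start = max(int(r.length) - span, int(r.centromere_end) + 2)
                chrom_segs[str(r.chrom)] = _carve(
                    chrom_segs[str(r.chrom)], start, int(r.length), 2, 1
                )
        for _ in range(n_lst):
            r = gm.iloc[rng.integers(len(gm))]
            arm_start = int(r.centromere_end) + 1
            arm_end = int(r.length)
            if arm_end - arm_start < 45 * MB:
                continue
            span = int(rng.uniform(12, 25) * MB)
            lo = int(rng.uniform(arm_start + 12 * MB, arm_end - span - 12 * MB))
            chrom_segs[str(r.chrom)] = _carve(
                chrom_segs[str(r.chrom)], lo, lo + span, 3, 1
            )
        for chrom, segs in chrom_segs.items():
            for s, e, ma, mi in segs:
                if e >= s:
                    rows.append((patient, chrom, s, e, ma, mi))
    return pd.DataFrame(
        rows, columns=["patient", "chrom", "start", "end", "major_cn", "minor_cn"]
    )


def _gene_blocks(n_genes: int) -> tuple[list[str], dict[str, slice]]:
    """Synthetic gene names with named markers followed by numbered filler."""
    named = (
        MITOTIC_GENES + CERAMIDE_GENES + CYTOLYTIC_GENES + HORMONE_GENES
        + CD8_MARKERS + MAST_MARKERS
    )
    filler = [f"G{i:05d}" for i in range(n_genes - len(named))]
    genes = named + filler
    # block layout over filler genes (offsets relative to full list)
    base = len(named)
    blocks = {
        "proliferation": slice(base, base + 120),
        "immune": slice(base + 120, base + 240),
        "escell": slice(base + 240, base + 300),
        "suppressor": slice(base + 300, base + 340),
    }
    return genes, blocks


def build_gene_sets(n_genes: int) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Gene sets aligned with the generator's planted expression programmes."""
    genes, blocks = _gene_blocks(n_genes)
    prolif = genes[blocks["proliferation"]]
    immune = genes[blocks["immune"]]
    escell = genes[blocks["escell"]]
    suppressor = genes[blocks["suppressor"]]
    gene_sets = {
        "GGI": prolif[:60] + MITOTIC_GENES,
        "ESC_MODULE": escell[:40],
        "STAT1_MODULE": immune[:40],
        "DANAHER_CD8": CD8_MARKERS,
        "DANAHER_MAST": MAST_MARKERS,
    }
    immunophenotype = {
        "MHC": immune[40:80],
        "immunomodulators": immune[80:120],
        "effector": immune[:40] + CYTOLYTIC_GENES,
        "suppressor": suppressor,
    }
    return gene_sets, immunophenotype


def _simulate_expression(cfg, traits, clinical):
    rng = cfg.rng("expression")
    genes, blocks = _gene_blocks(cfg.n_genes)
    n_genes, n = len(genes), len(traits)
    gene_mean = rng.normal(4.0, 1.6, n_genes)  # log2 scale
    lengths = pd.Series(
        rng.integers(500, 5001, n_genes), index=pd.Index(genes, name="gene"),
        name="length",
    )
    shift = np.zeros((n_genes, n))
    prolif = _trait(traits, "proliferation")
    immune = _trait(traits, "immune")
    dys = _trait(traits, "dysfunction")
    shift[blocks["proliferation"]] += 0.85 * prolif
    shift[blocks["immune"]] += 0.85 * immune
    shift[blocks["escell"]] += 0.6 * prolif + 0.2 * rng.standard_normal(n)
    shift[blocks["suppressor"]] += 0.7 * dys
    gidx = {g: k for k, g in enumerate(genes)}
    for g in MITOTIC_GENES:
        shift[gidx[g]] += 0.85 * prolif
    for g in CERAMIDE_GENES:
        shift[gidx[g]] += 0.1 * rng.standard_normal(n)
    for g in CYTOLYTIC_GENES + CD8_MARKERS:
        shift[gidx[g]] += 0.9 * immune
    for g in MAST_MARKERS:
        shift[gidx[g]] += 0.7 * dys
    er = clinical["er_status"].to_numpy()
    her2 = clinical["her2_status"].to_numpy()
    shift[gidx["ESR1"]] += 2.5 * er
    shift[gidx["PGR"]] += 2.0 * er
    shift[gidx["ERBB2"]] += 2.5 * her2
    lib = np.exp(rng.normal(0.0, 0.25, n))
    noise = rng.normal(0.0, 0.25, (n_genes, n))
    mu = 2.0 ** (gene_mean[:, None] + shift + noise) * lib[None, :] / 16.0
    counts = rng.poisson(mu)
    expr = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                        columns=traits.index)
    return expr, lengths


def _simulate_cells_table(cfg, traits):
    rng = cfg.rng("cells")
    lam = cfg.base_lymphocyte_intensity * np.exp(0.8 * _trait(traits, "immune"))
    frames = []
    for i, patient in enumerate(traits.index):
        mix_raw = rng.dirichlet([18, 12, 6])
        rates = {
            "cancer": cfg.base_lymphocyte_intensity * 2.5 * mix_raw[0] / 0.5,
            "stromal": cfg.base_lymphocyte_intensity * 2.0 * mix_raw[1] / 0.33,
            "lymphocyte": float(lam[i]),
        }
        frames.append(
            simulate_cells(rates, cfg.cell_window, rng=rng, slide_id=patient)
        )
    cells = pd.concat(frames, ignore_index=True)
    return cells, pd.Series(lam, index=traits.index, name="lymphocyte_intensity")


def _simulate_affinity_tables(cfg, traits, mutations):
    rng = cfg.rng("affinities")
    n_mut = mutations.groupby("patient").size().reindex(traits.index, fill_value=0)
    frames = []
    for patient in traits.index:
        n_cand = int(min(3 * n_mut[patient], 400))
        frames.append(simulate_affinities(n_cand, rng, patient=patient))
    aff = pd.concat(frames, ignore_index=True)
    passing = (
        (aff["mutant_nm"] < 500)
        & (aff["mutant_nm"] < aff["wildtype_nm"])
        & (aff["tpm"] > 1)
    )
    n_pass = (
        aff[passing].groupby("patient").size().reindex(traits.index, fill_value=0)
    )
    return aff, n_pass


def _simulate_hla(cfg, traits, latent):
    rng = cfg.rng("hla")
    p_loh = _sigmoid(-1.7 - 0.7 * _signal(cfg, traits))
    rows = []
    for i, patient in enumerate(traits.index):
        has_loh = rng.random() < p_loh[i]
        lost = rng.integers(0, 6) if has_loh else -1
        for a, allele in enumerate(["A1", "A2", "B1", "B2", "C1", "C2"]):
            if a == lost:
                cn = rng.uniform(0.0, 0.4)
                p = rng.uniform(1e-6, 0.04)
            else:
                cn = rng.uniform(0.7, 1.3)
                p = rng.uniform(0.05, 1.0)
            rows.append((patient, allele, cn, p))
    return pd.DataFrame(rows, columns=["patient", "allele", "cn", "p_value"])


def _simulate_immune_scores(cfg, traits):
    rng = cfg.rng("immune_scores")
    n = len(traits)
    return pd.DataFrame(
        {
            "dysfunction": _trait(traits, "dysfunction") + 0.35 * rng.standard_normal(n),
            "exclusion": _trait(traits, "exclusion") + 0.35 * rng.standard_normal(n),
        },
        index=traits.index,
    )


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a full synthetic multi-omic cohort bundle.

    All tables share the patient identifier; identical configs (including the
    seed) produce identical bundles.
    """
    traits, latent, rcb = _simulate_latent(config)
    clinical = _simulate_clinical(config, traits, latent, rcb)
    mutations, true_ccf, sig_weights, _ = _simulate_mutation_tables(
        config, traits, latent
    )
    segments = _simulate_segments(config, traits)
    expression, lengths = _simulate_expression(config, traits, clinical)
    gene_sets, immunophenotype = build_gene_sets(config.n_genes)
    cells, intensity = _simulate_cells_table(config, traits)
    affinities, n_neo = _simulate_affinity_tables(config, traits, mutations)
    hla = _simulate_hla(config, traits, latent)
    immune_scores = _simulate_immune_scores(config, traits)
    gt = GroundTruth(
        latent=latent,
        traits=traits,
        rcb_class=rcb,
        true_ccf=true_ccf,
        signature_weights=sig_weights,
        lymphocyte_intensity=intensity,
        n_neoantigens=n_neo,
    )
    return CohortBundle(
        clinical=clinical,
        mutations=mutations,
        segments=segments,
        expression=expression,
        gene_lengths=lengths,
        gene_sets=gene_sets,
        immunophenotype_groups=immunophenotype,
        cells=cells,
        affinities=affinities,
        hla=hla,
        immune_scores=immune_scores,
        ground_truth=gt,
        config=config,
    )
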