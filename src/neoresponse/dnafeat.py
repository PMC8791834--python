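"""DNA-level tumour features from somatic mutation tables and allele-specific copy number.

Implements cancer cell fraction (CCF) estimation and clonality calls, tumour
mutation burden, mutational-signature exposure fitting, homologous recombination
deficiency (HRD) scar scores (TAI + LOH + LST), genome-altered fraction, HLA
loss-of-heterozygosity calls and neoantigen filtering.

Conventions: genomic coordinates are 1-based inclusive; CN_normal refers to the
germline copy number at the mutant locus (2 on autosomes) and CN_tumour to the
total tumour copy number. Mutation multiplicity is not modelled: the CCF point
estimate is VAF/p * ((1-p)*CN_normal + p*CN_tumour), which treats every mutation
as present on a single copy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from statsmodels.stats.proportion import proportion_confint

#: Exome footprint (megabases) used to convert mutation counts to mutations/Mb.
EXOME_FOOTPRINT_MB = 45.54

#: Signatures regarded as "clock-like" (age-associated) when computing the
#: non-clock fraction of a signature decomposition.
CLOCK_SIGNATURES = ("1", "5")

#: Exposure weights below this value are zeroed before renormalization.
SIGNATURE_DISCARD_THRESHOLD = 0.06

#: Minimum number of mutations for a signature decomposition to be attempted.
SIGNATURE_MIN_MUTATIONS = 10


# ---------------------------------------------------------------------------
# Clonal reconstruction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CcfCall:
    """CCF point estimate with confidence interval and clonality label.

    ``clonal`` is True iff the 95% CI on CCF overlaps 1 (low <= 1 <= high);
    every other mutation is subclonal.  Note the rule as stated also labels
    intervals lying entirely *above* 1 as subclonal; such calls carry
    ``above_one=True`` so callers can audit them.
    """

    ccf: float
    ci_low: float | None = None
    ci_high: float | None = None
    clonal: bool | None = None
    above_one: bool = False

    @property
    def clonality(self) -> str:
        return "clonal" if self.clonal else "subclonal"


def _ccf_multiplier(purity: float, cn_normal: float, cn_tumour: float) -> float:
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if cn_normal < 0 or cn_tumour < 0:
        raise ValueError("copy numbers must be non-negative")
    return ((1.0 - purity) * cn_normal + purity * cn_tumour) / purity


def compute_ccf(
    vaf: float, purity: float, cn_normal: float = 2, cn_tumour: float = 2
) -> float:
    """Cancer cell fraction point estimate.

    CCF = VAF/p * ((1-p)*CN_normal + p*CN_tumour).  Values above 1 are
    reported as-is (they arise from sampling noise, purity error or
    multi-copy mutations, which this estimator does not model).
    """
    if not 0.0 <= vaf <= 1.0:
        raise ValueError(f"VAF must be in [0, 1], got {vaf}")
    return vaf * _ccf_multiplier(purity, cn_normal, cn_tumour)


def classify_clonality(
    alt_reads: int,
    total_reads: int,
    purity: float,
    cn_normal: float = 2,
    cn_tumour: float = 2,
    alpha: float = 0.05,
) -> CcfCall:
    """CCF with a binomial CI on VAF mapped to the CCF scale, plus clonality.

    The CI on alt/total is a Wilson score interval; both bounds are scaled by
    the same multiplier as the point estimate.  A mutation is clonal iff the
    CI contains 1.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if alt_reads < 0 or alt_reads > total_reads:
        raise ValueError("alt_reads must be in [0, total_reads]")
    mult = _ccf_multiplier(purity, cn_normal, cn_tumour)
    vaf = alt_reads / total_reads
    low, high = proportion_confint(alt_reads, total_reads, alpha=alpha, method="wilson")
    ci_low, ci_high = low * mult, high * mult
    clonal = ci_low <= 1.0 <= ci_high
    return CcfCall(
        ccf=vaf * mult,
        ci_low=ci_low,
        ci_high=ci_high,
        clonal=clonal,
        above_one=ci_low > 1.0,
    )


def classify_mutations(muts: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Vectorised clonality classification over a mutation table.

    Expects columns alt_reads, total_reads, purity, cn_normal, cn_tumour.
    Rows with missing purity/CN or zero depth are marked unclassifiable
    (``classifiable=False``) rather than raising.
    """
    out = muts.copy()
    cols = ["alt_reads", "total_reads", "purity", "cn_normal", "cn_tumour"]
    ok = out[cols].notna().all(axis=1)
    ok &= out["total_reads"] > 0
    ok &= (out["purity"] > 0) & (out["purity"] <= 1)
    ok &= out["cn_tumour"] >= 0

    mult = np.where(
        ok,
        ((1 - out["purity"]) * out["cn_normal"] + out["purity"] * out["cn_tumour"])
        / out["purity"].where(out["purity"] > 0, np.nan),
        np.nan,
    )
    alt = out["alt_reads"].to_numpy(float)
    tot = out["total_reads"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        low, high = proportion_confint(
            np.where(ok, alt, 0), np.where(ok, tot, 1), alpha=alpha, method="wilson"
        )
        out["ccf"] = np.where(ok, alt / tot * mult, np.nan)
    out["ccf_low"] = np.where(ok, low * mult, np.nan)
    out["ccf_high"] = np.where(ok, high * mult, np.nan)
    out["classifiable"] = ok
    out["clonal"] = ok & (out["ccf_low"] <= 1.0) & (out["ccf_high"] >= 1.0)
    return out


def pct_subclonal(muts: pd.DataFrame, alpha: float = 0.05) -> float:
    """Percentage of classifiable mutations called subclonal (0-100).

    Returns NaN when no mutation is classifiable; a patient with zero
    classifiable mutations has missing, not zero, subclonality.
    """
    if "clonal" not in muts.columns or "classifiable" not in muts.columns:
        muts = classify_mutations(muts, alpha=alpha)
    cls = muts[muts["classifiable"]]
    if len(cls) == 0:
        return float("nan")
    return 100.0 * float((~cls["clonal"]).sum()) / len(cls)


def compute_tmb(n_mutations: int, footprint_mb: float = EXOME_FOOTPRINT_MB) -> float:
    """Tumour mutation burden: somatic mutations per megabase sequenced."""
    if n_mutations < 0:
        raise ValueError("mutation count cannot be negative")
    return n_mutations / footprint_mb


# ---------------------------------------------------------------------------
# Mutational signatures
# ---------------------------------------------------------------------------


@dataclass
class SignatureExposure:
    """Non-negative signature weights on the simplex plus fit diagnostics."""

    weights: pd.Series  # index: signature names, values sum to 1 (or all 0)
    reconstruction_error: float
    n_mutations: int

    def nonzero(self) -> pd.Series:
        return self.weights[self.weights > 0]


def fit_signature_exposures(
    catalogue: np.ndarray | pd.Series,
    reference: pd.DataFrame,
    n_mutations: int | None = None,
    discard_threshold: float = SIGNATURE_DISCARD_THRESHOLD,
) -> SignatureExposure | None:
    """Decompose a 96-channel trinucleotide catalogue into reference signatures.

    Non-negative least squares against the (column-normalized) reference
    matrix; weights below ``discard_threshold`` are zeroed and the remainder
    renormalized to sum to 1.  Tumours with <= 10 mutations return ``None``
    (no-result marker) — too few mutations to decompose reliably.
    """
    cat = np.asarray(catalogue, dtype=float).ravel()
    if cat.shape[0] != reference.shape[0]:
        raise ValueError(
            f"catalogue has {cat.shape[0]} channels, reference {reference.shape[0]}"
        )
    colsums = reference.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise ValueError("reference signature columns must each sum to 1")
    if n_mutations is None:
        n_mutations = int(round(cat.sum()))
    if n_mutations <= SIGNATURE_MIN_MUTATIONS:
        return None
    total = cat.sum()
    if total <= 0:
        raise ValueError("catalogue is empty")
    target = cat / total
    w, _ = nnls(reference.to_numpy(float), target)
    w = np.where(w < discard_threshold, 0.0, w)
    if w.sum() > 0:
        w = w / w.sum()
    resid = target - reference.to_numpy(float) @ w
    return SignatureExposure(
        weights=pd.Series(w, index=reference.columns),
        reconstruction_error=float(np.sqrt(np.sum(resid**2))),
        n_mutations=n_mutations,
    )


def normalize_exposures(
    exposure: SignatureExposure,
    reference_signature: str = "1",
    pseudo_count: float = 0.01,
    clock_signatures: tuple[str, ...] = CLOCK_SIGNATURES,
) -> tuple[pd.Series, float]:
    """Per-signature log2 ratio versus the age (clock) signature, plus the
    non-clock fraction.

    ratio_s = log2((w_s + c) / (w_ref + c)) with pseudo-count c keeping the
    ratio finite when the reference weight is 0.  Non-clock fraction is
    1 - sum of clock-signature weights.
    """
    w = exposure.weights
    ref = float(w.get(reference_signature, 0.0))
    ratios = np.log2((w + pseudo_count) / (ref + pseudo_count))
    clock = sum(float(w.get(s, 0.0)) for s in clock_signatures)
    return ratios, 1.0 - clock


# ---------------------------------------------------------------------------
# HRD scar score
# ---------------------------------------------------------------------------

MB = 1_000_000


@dataclass(frozen=True)
class HrdScore:
    """Genomic scar components: telomeric allelic imbalance, large LOH
    segments and large-scale state transitions, plus their sum."""

    tai: int
    loh: int
    lst: int

    @property
    def total(self) -> int:
        return self.tai + self.loh + self.lst


def _check_segments(segs: pd.DataFrame) -> None:
    starts = segs["start"].to_numpy(np.int64)
    ends = segs["end"].to_numpy(np.int64)
    if (starts > ends).any():
        raise ValueError("segment with start > end")
    chrom_codes = pd.factorize(segs["chrom"])[0]
    order = np.lexsort((starts, chrom_codes))
    c, s, e = chrom_codes[order], starts[order], ends[order]
    same = c[1:] == c[:-1]
    if (same & (s[1:] <= e[:-1])).any():
        bad = segs["chrom"].to_numpy()[order][1:][same & (s[1:] <= e[:-1])][0]
        raise ValueError(f"overlapping segments on chromosome {bad}")


def _split_at_centromere(arr: np.ndarray, cen_start: int, cen_end: int):
    """Split a (start, end, major, minor) array into p-arm and q-arm pieces."""
    p = arr[arr[:, 0] < cen_start].copy()
    if len(p):
        p[:, 1] = np.minimum(p[:, 1], cen_start - 1)
        p = p[p[:, 1] >= p[:, 0]]
    q = arr[arr[:, 1] > cen_end].copy()
    if len(q):
        q[:, 0] = np.maximum(q[:, 0], cen_end + 1)
        q = q[q[:, 1] >= q[:, 0]]
    return p, q


def _lst_on_arm(arm: np.ndarray, min_flank: int = 10 * MB, max_gap: int = 3 * MB,
                min_keep: int = 3 * MB) -> int:
    """Large-scale transitions on one chromosome arm.

    Segments shorter than 3 Mb are removed, adjacent segments with identical
    allele-specific CN (and < 3 Mb apart) are merged, and a breakpoint counts
    when both flanking segments are >= 10 Mb and separated by < 3 Mb.
    """
    g = arm[(arm[:, 1] - arm[:, 0] + 1) >= min_keep]
    if len(g) < 2:
        return 0
    g = g[np.argsort(g[:, 0])]
    rows = [list(g[0])]
    for s, e, ma, mi in g[1:]:
        last = rows[-1]
        if last[2] == ma and last[3] == mi and s - last[1] - 1 < max_gap:
            last[1] = e
        else:
            rows.append([s, e, ma, mi])
    count = 0
    for a, b in zip(rows, rows[1:]):
        len_a = a[1] - a[0] + 1
        len_b = b[1] - b[0] + 1
        gap = b[0] - a[1] - 1
        if len_a >= min_flank and len_b >= min_flank and gap < max_gap:
            count += 1
    return count


def compute_hrd(segments: pd.DataFrame, genome_model: pd.DataFrame) -> HrdScore:
    """HRD scar score from allele-specific copy-number segments.

    Components (per the published scar definitions):

    * **LOH** — segments with minor CN 0 and major CN > 0, longer than 15 Mb,
      not spanning the whole chromosome.
    * **TAI** — allelic-imbalance segments (major != minor) that reach a
      telomere and do not cross the centromere.
    * **LST** — per-arm breakpoints between >= 10 Mb segments separated by
      < 3 Mb, after removing segments < 3 Mb.

    ``genome_model`` must have columns chrom, length, centromere_start,
    centromere_end.
    """
    _check_segments(segments)
    gm = genome_model.set_index("chrom")
    tai = loh = lst = 0
    for chrom, grp in segments.groupby("chrom", sort=False):
        if chrom not in gm.index:
            raise ValueError(f"chromosome {chrom} absent from genome model")
        length = int(gm.loc[chrom, "length"])
        cen_s = int(gm.loc[chrom, "centromere_start"])
        cen_e = int(gm.loc[chrom, "centromere_end"])
        arr = grp[["start", "end", "major_cn", "minor_cn"]].to_numpy(np.int64)
        arr = arr[np.argsort(arr[:, 0])]
        start, end, major, minor = arr.T
        seg_len = end - start + 1
        whole = (start <= 1) & (end >= length)
        loh += int(
            ((minor == 0) & (major > 0) & (seg_len > 15 * MB) & ~whole).sum()
        )
        imbalance = major != minor
        touches_telomere = (start <= 1) | (end >= length)
        crosses_cen = (start < cen_s) & (end > cen_e)
        tai += int((imbalance & touches_telomere & ~crosses_cen & ~whole).sum())
        p_arm, q_arm = _split_at_centromere(arr, cen_s, cen_e)
        lst += _lst_on_arm(p_arm) + _lst_on_arm(q_arm)
    return HrdScore(tai=tai, loh=loh, lst=lst)


def genome_altered_fraction(segments: pd.DataFrame, ploidy: float = 2.0) -> float:
    """Length-weighted fraction of the covered genome whose total copy number
    differs from round(ploidy)."""
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    _check_segments(segments)
    lengths = (segments["end"] - segments["start"] + 1).to_numpy(float)
    covered = lengths.sum()
    if covered <= 0:
        raise ValueError("segments cover zero genome")
    total_cn = (segments["major_cn"] + segments["minor_cn"]).to_numpy(float)
    altered = lengths[total_cn != round(ploidy)].sum()
    return float(altered / covered)


# ---------------------------------------------------------------------------
# HLA LOH and neoantigens
# ---------------------------------------------------------------------------

HLA_LOH_CN_THRESHOLD = 0.5
HLA_LOH_ALPHA = 0.05


def call_hla_loh(
    allele_estimates: pd.DataFrame,
    cn_threshold: float = HLA_LOH_CN_THRESHOLD,
    alpha: float = HLA_LOH_ALPHA,
) -> pd.DataFrame:
    """Flag HLA class I alleles undergoing LOH.

    An allele is lost iff its estimated copy number is below 0.5 *and* the
    loss is statistically significant (p < alpha).  Expects columns
    patient, allele, cn, p_value; rows with missing p are skipped with a
    warning column rather than dropped silently.
    """
    out = allele_estimates.copy()
    if (out["cn"] < 0).any():
        raise ValueError("allele copy number cannot be negative")
    usable = out["p_value"].notna()
    out["loh"] = usable & (out["cn"] < cn_threshold) & (out["p_value"] < alpha)
    out["skipped"] = ~usable
    return out


def patient_hla_loh(allele_calls: pd.DataFrame) -> pd.Series:
    """Any-allele LOH flag per patient from `call_hla_loh` output."""
    return allele_calls.groupby("patient")["loh"].any()


def hla_loh_impact(
    allele_calls: pd.DataFrame, neoepitopes: pd.DataFrame
) -> tuple[float, float]:
    """Summarize the presentation impact of HLA LOH events.

    Returns ``(pct_unpresentable, frac_events_lost_ge_retained)`` where
    pct_unpresentable is the percentage of neoepitopes whose presenting
    alleles are all lost, and the second value is the fraction of LOH events
    (lost alleles) that presented at least as many neoepitopes as the
    patient's best retained allele.  Neoepitope table needs columns patient,
    peptide, allele.
    """
    lost = set(
        map(tuple, allele_calls.loc[allele_calls["loh"], ["patient", "allele"]].values)
    )
    if len(neoepitopes) == 0:
        return 0.0, float("nan")
    presentable = 0
    total = 0
    for (patient, peptide), grp in neoepitopes.groupby(["patient", "peptide"]):
        total += 1
        if any((patient, a) not in lost for a in grp["allele"]):
            presentable += 1
    pct_unpresentable = 100.0 * (total - presentable) / total if total else 0.0

    counts = neoepitopes.groupby(["patient", "allele"]).size()
    events = 0
    dominant = 0
    for patient, allele in lost:
        n_lost = counts.get((patient, allele), 0)
        retained = [
            a
            for a in allele_calls.loc[
                allele_calls["patient"] == patient, "allele"
            ].unique()
            if (patient, a) not in lost
        ]
        n_retained = max((counts.get((patient, a), 0) for a in retained), default=0)
        events += 1
        if n_lost >= n_retained:
            dominant += 1
    frac = dominant / events if events else float("nan")
    return pct_unpresentable, frac


NEOANTIGEN_AFFINITY_NM = 500.0
NEOANTIGEN_MIN_TPM = 1.0


def filter_neoantigens(
    candidates: pd.DataFrame,
    affinity_nm: float = NEOANTIGEN_AFFINITY_NM,
    min_tpm: float = NEOANTIGEN_MIN_TPM,
) -> pd.DataFrame:
    """Retain candidate neoepitopes passing the three filters.

    Kept iff mutant binding affinity < 500 nM (strict), mutant binds more
    strongly than the wild-type peptide (mutant nM < wild-type nM), and the
    source transcript is expressed above 1 TPM (strict).  Peptide lengths
    must already be 8-11 residues.
    """
    req = {"length", "mutant_nm", "wildtype_nm", "tpm"}
    missing = req - set(candidates.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    if (candidates["mutant_nm"] < 0).any() or (candidates["wildtype_nm"] < 0).any():
        raise ValueError("binding affinities cannot be negative")
    if not candidates["length"].isin([8, 9, 10, 11]).all():
        raise ValueError("peptide lengths must be between 8 and 11 residues")
    keep = (
        (candidates["mutant_nm"] < affinity_nm)
        & (candidates["mutant_nm"] < candidates["wildtype_nm"])
        & (candidates["tpm"] > min_tpm)
    )
    return candidates[keep]


def driver_flags(
    muts: pd.DataFrame, driver_genes: list[str], patients: list[str] | None = None
) -> pd.DataFrame:
    """Binary per-patient flags: 1 iff >= 1 somatic mutation in the gene."""
    if patients is None:
        patients = sorted(muts["patient"].unique())
    flags = pd.DataFrame(0, index=pd.Index(patients, name="patient"),
                         columns=driver_genes, dtype=int)
    hit = muts[muts["gene"].isin(driver_genes)]
    for (patient, gene), _ in hit.groupby(["patient", "gene"]):
        if patient in flags.index:
            flags.loc[patient, gene] = 1
    return flags


def cohort_counts(
    muts: pd.DataFrame, clinical: pd.DataFrame, drivers: tuple[str, ...] = ("TP53", "PIK3CA")
) -> dict:
    """Descriptive cohort counts: total mutation records, per-driver mutated
    case counts, and RCB class counts from a clinical table with `rcb_class`."""
    out = {"n_mutations": int(len(muts))}
    for g in drivers:
        out[f"n_{g.lower()}_cases"] = int(
            muts.loc[muts["gene"] == g, "patient"].nunique()
        )
    rcb = clinical["rcb_class"].value_counts()
    for cls in ["pCR", "RCB-I", "RCB-II", "RCB-III"]:
        out[f"n_{cls}"] = int(rcb.get(cls, 0))
    return out
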