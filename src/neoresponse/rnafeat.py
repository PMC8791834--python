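"""Transcriptomic feature derivation.

Expression normalization follows the chain TMM -> FPKM -> TPM: trimmed mean of
M-values scale factors correct library composition, FPKM divides by gene length
and effective library size, and rescaling each sample to a million yields TPM.
On top of the TPM/log-TPM layers the module computes single-sample gene-set
enrichment (ssGSEA), metagene scores (cytolytic, taxane-response, Danaher-style
log-geometric means), immunophenotype class z-scores and the centred log matrix
used as input by T cell dysfunction/exclusion scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Raw counts (genes x samples) with derived normalized layers."""

    counts: pd.DataFrame
    lengths: pd.Series  # bp per gene, aligned with counts.index
    tmm_factors: pd.Series
    fpkm: pd.DataFrame
    tpm: pd.DataFrame
    log_tpm: pd.DataFrame  # log2(TPM + 1)


def _tmm_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> float:
    """TMM scale factor of one library against the reference library.

    Doubly trimmed (30% on M, 5% on A) weighted mean of the log expression
    ratios, with inverse asymptotic-variance weights (the standard TMM
    estimator with weighting on).
    """
    keep = (obs > 0) & (ref > 0)
    obs_p, ref_p = obs[keep] / lib_obs, ref[keep] / lib_ref
    m = np.log2(obs_p / ref_p)
    a = 0.5 * np.log2(obs_p * ref_p)
    # guard against infinite A when a proportion underflows
    finite = np.isfinite(m) & np.isfinite(a)
    m, a = m[finite], a[finite]
    o, r = obs[keep][finite], ref[keep][finite]
    if m.size == 0 or np.max(np.abs(m)) < 1e-10:
        return 1.0
    m_lo, m_hi = np.quantile(m, [m_trim, 1 - m_trim])
    a_lo, a_hi = np.quantile(a, [a_trim, 1 - a_trim])
    sel = (m >= m_lo) & (m <= m_hi) & (a >= a_lo) & (a <= a_hi)
    if not sel.any():
        return 1.0
    w = 1.0 / ((lib_obs - o[sel]) / (lib_obs * o[sel])
               + (lib_ref - r[sel]) / (lib_ref * r[sel]))
    f = np.sum(w * m[sel]) / np.sum(w)
    return float(2.0**f)


def tmm_factors(counts: pd.DataFrame) -> pd.Series:
    """TMM normalization factors for every sample (column).

    The reference sample is the one whose 75th percentile of counts-per-total
    is closest to the mean 75th percentile.  Factors are normalized so their
    geometric mean is 1, matching the usual convention.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0)
    zero = lib[lib == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    uq = counts.apply(lambda c: np.quantile(c[c > 0] / c.sum(), 0.75), axis=0)
    ref_sample = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy(float)
    lib_ref = float(lib[ref_sample])
    factors = {}
    for s in counts.columns:
        if s == ref_sample:
            factors[s] = 1.0
        else:
            factors[s] = _tmm_factor(
                counts[s].to_numpy(float), ref, float(lib[s]), lib_ref
            )
    f = pd.Series(factors)[counts.columns]
    return f / np.exp(np.mean(np.log(f)))


def tmm_tpm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> ExpressionMatrix:
    """Full normalization chain: TMM scale factors -> FPKM -> TPM.

    FPKM_gs = count_gs / (effective library size_s / 1e6) / (length_g / 1e3),
    where the effective library size is the raw library size times the TMM
    factor; TPM rescales each sample's FPKM column to sum to 1e6.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("every gene needs a length")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    factors = tmm_factors(counts)
    eff_lib = counts.sum(axis=0) * factors
    fpkm = counts.div(eff_lib / 1e6, axis=1).div(lengths / 1e3, axis=0)
    tpm = fpkm.div(fpkm.sum(axis=0), axis=1) * 1e6
    return ExpressionMatrix(
        counts=counts,
        lengths=lengths,
        tmm_factors=factors,
        fpkm=fpkm,
        tpm=tpm,
        log_tpm=np.log2(tpm + 1.0),
    )


# ---------------------------------------------------------------------------
# Gene sets and single-sample enrichment
# ---------------------------------------------------------------------------


def read_gmt(path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: [gene symbols]}."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, name] + list(genes)) + "\n")


def _resolve_set(
    genes: list[str],
    matrix_genes: pd.Index,
    min_frac: float = 0.5,
    alias: dict[str, str] | None = None,
):
    """Map set symbols onto matrix genes, via an optional alias map.

    Unmapped genes are dropped with a warning as long as at least
    ``min_frac`` of the set maps; below that it is an error.
    """
    if alias:
        genes = [alias.get(g, g) for g in genes]
    present = [g for g in dict.fromkeys(genes) if g in matrix_genes]
    missing = [g for g in dict.fromkeys(genes) if g not in matrix_genes]
    if not present:
        raise ValueError("no gene of the set is present in the expression matrix")
    if missing:
        if len(present) < min_frac * (len(present) + len(missing)):
            raise ValueError(
                f"fewer than {min_frac:.0%} of set genes map to the matrix; "
                f"missing: {missing[:10]}..."
            )
        warnings.warn(f"{len(missing)} set gene(s) absent from matrix: {missing[:10]}")
    return present


def ssgsea_score(
    expr: pd.DataFrame,
    gene_set: list[str],
    weight: float = 0.25,
    normalize: bool = True,
    alias: dict[str, str] | None = None,
) -> pd.Series:
    """Single-sample GSEA enrichment score per sample.

    For each sample, genes are ranked by expression (descending); the score is
    the integrated difference between the weighted empirical CDF of in-set
    genes (weights |rank|^0.25) and the unweighted CDF of out-of-set genes.
    Rank-based, hence invariant to any strictly increasing per-sample
    transform of expression.  With ``normalize``, scores are divided by the
    absolute range of scores across samples.
    """
    members = _resolve_set(gene_set, expr.index, alias=alias)
    n_genes = expr.shape[0]
    in_set = expr.index.isin(members)
    scores = {}
    for s in expr.columns:
        order = np.argsort(-expr[s].to_numpy(), kind="stable")
        ranks = np.empty(n_genes)
        ranks[order] = np.arange(n_genes, 0, -1)  # descending expr -> high rank
        hits = in_set
        w = np.abs(ranks) ** weight
        w_hit = np.where(hits, w, 0.0)
        sorted_idx = order  # walk genes from highest to lowest expression
        w_walk = w_hit[sorted_idx]
        hit_cdf = np.cumsum(w_walk) / w_walk.sum()
        miss = (~hits)[sorted_idx].astype(float)
        miss_cdf = np.cumsum(miss) / miss.sum()
        scores[s] = float(np.sum(hit_cdf - miss_cdf))
    out = pd.Series(scores, name="ssgsea")
    if normalize:
        rng = out.max() - out.min()
        if rng > 0:
            out = out / rng
    return out


def zscore_set_score(expr: pd.DataFrame, gene_set: list[str]) -> pd.Series:
    """Alternative single-sample score: mean per-gene z-score of set members."""
    members = _resolve_set(gene_set, expr.index)
    sub = expr.loc[members]
    sd = sub.std(axis=1, ddof=1)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd.where(sd > 0, np.inf), axis=0)
    return z.mean(axis=0)


def single_sample_score(
    expr: pd.DataFrame, gene_set: list[str], method: str = "ssgsea"
) -> pd.Series:
    if method == "ssgsea":
        return ssgsea_score(expr, gene_set)
    if method == "zscore":
        return zscore_set_score(expr, gene_set)
    raise ValueError(f"unknown single-sample method: {method}")


# ---------------------------------------------------------------------------
# Metagenes
# ---------------------------------------------------------------------------

MITOTIC_METAGENE = ["BUB1B", "CDK1", "AURKB", "TTK"]
CERAMIDE_METAGENE = ["UGCG", "CERT1"]
CYTOLYTIC_GENES = ["GZMA", "PRF1"]


def metagene_score(
    tpm: pd.DataFrame,
    genes: list[str],
    mode: str = "geomean",
    offset: float = 0.01,
    genes_b: list[str] | None = None,
) -> pd.Series:
    """Summary score over a small gene list, per sample.

    Modes: ``geomean`` = exp(mean(ln(TPM + offset))); ``log_geomean`` =
    mean(log2(TPM + offset)); ``difference`` = geomean(genes) -
    geomean(genes_b) (used by the taxane-response metagene with mitotic vs
    ceramide gene lists).
    """
    if (tpm < 0).to_numpy().any():
        raise ValueError("TPM values cannot be negative")
    members = _resolve_set(genes, tpm.index)
    sub = tpm.loc[members] + offset
    if mode == "geomean":
        return np.exp(np.log(sub).mean(axis=0))
    if mode == "log_geomean":
        return np.log2(sub).mean(axis=0)
    if mode == "difference":
        if genes_b is None:
            raise ValueError("difference mode needs genes_b")
        b = tpm.loc[_resolve_set(genes_b, tpm.index)] + offset
        return np.exp(np.log(sub).mean(axis=0)) - np.exp(np.log(b).mean(axis=0))
    raise ValueError(f"unknown metagene mode: {mode}")


def cytolytic_score(tpm: pd.DataFrame) -> pd.Series:
    """Immune cytolytic activity: geometric mean of GZMA and PRF1 TPM
    (0.01 offset)."""
    return metagene_score(tpm, CYTOLYTIC_GENES, mode="geomean", offset=0.01)


def taxane_metagene(tpm: pd.DataFrame, offset: float = 0.01) -> pd.Series:
    """Taxane-response metagene: mitotic geomean minus ceramide geomean."""
    return metagene_score(
        tpm, MITOTIC_METAGENE, mode="difference", offset=offset,
        genes_b=CERAMIDE_METAGENE,
    )


def danaher_scores(
    tpm: pd.DataFrame, cell_sets: dict[str, list[str]], offset: float = 0.01
) -> pd.DataFrame:
    """Danaher-style cell-type scores: log2 geometric mean of marker TPM."""
    return pd.DataFrame(
        {
            cell: metagene_score(tpm, genes, mode="log_geomean", offset=offset)
            for cell, genes in cell_sets.items()
        }
    )


def immunophenotype_zscores(
    tpm: pd.DataFrame, gene_groups: dict[str, list[str]]
) -> pd.DataFrame:
    """Per-class mean z-score per sample over immunophenotype gene groups
    (MHC molecules, immunomodulators, effector cells, suppressor cells).

    Each gene is z-scored across samples; zero-variance genes get z = 0 with
    a warning.  Class score = mean z over the class's genes.
    """
    out = {}
    for cls, genes in gene_groups.items():
        members = _resolve_set(genes, tpm.index)
        sub = tpm.loc[members]
        sd = sub.std(axis=1, ddof=1)
        flat = sd[sd == 0]
        if len(flat):
            warnings.warn(f"zero-variance gene(s) in class {cls}: {list(flat.index)[:5]}")
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd.where(sd > 0, np.inf), axis=0)
        out[cls] = z.mean(axis=0)
    return pd.DataFrame(out)


def tide_normalize(tpm: pd.DataFrame) -> pd.DataFrame:
    """Input normalization for dysfunction/exclusion scoring: log2(TPM + 1)
    centred by subtracting each sample's mean log expression over all genes."""
    log = np.log2(tpm + 1.0)
    return log.sub(log.mean(axis=0), axis=1)


def dichotomize_high(scores: pd.Series) -> pd.Series:
    """Boolean flag per sample: score strictly above the cohort mean."""
    if len(scores) < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    return scores > scores.mean()
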