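"""Microsatellite statistics.

Per-locus diversity (Ho, unbiased He, rarefied allelic richness),
differentiation estimators in the bias-corrected GST family (FST, Hedrick's
standardized F'ST, Jost's D), Goldstein's (delta-mu)^2 distance, the
heterozygosity-excess bottleneck test, and principal coordinates analysis.

Multilocus statistics combine loci as ratios of locus-averaged components
(not means of per-locus ratios). Missing genotypes are excluded per locus;
an individual is treated as genotyped at a locus only when both alleles are
called.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import wilcoxon

from phylopop.io_formats import GenotypeTable, PopulationMap
from phylopop.mtdna_stats import fdr_correct

__all__ = [
    "LocusDiversity",
    "DifferentiationResult",
    "DeltaMuResult",
    "BottleneckResult",
    "Ordination",
    "locus_diversity",
    "differentiation",
    "delta_mu_squared",
    "bottleneck_test",
    "pcoa",
    "unbiased_expected_heterozygosity",
    "rarefied_allelic_richness",
]


# ---------------------------------------------------------------------------
# Per-locus preprocessing


def _locus_arrays(gt: GenotypeTable, popmap: PopulationMap):
    """Per locus: (allele index matrix (n,2) with -1 missing, allele sizes).

    An individual is genotyped only if both alleles are called; half-calls
    are dropped. Returns also the per-sample population label codes.
    """
    pops = popmap.populations
    pop_index = {p: k for k, p in enumerate(pops)}
    samples = [s for s in gt.sample_ids if s in popmap.assignments]
    rows = [gt.sample_ids.index(s) for s in samples]
    labels = np.array([pop_index[popmap.assignments[s]] for s in samples])
    per_locus = []
    for locus_idx in range(len(gt.locus_ids)):
        calls = gt.calls[rows, locus_idx, :]
        genotyped = (calls >= 0).all(axis=1)
        sizes = np.unique(calls[genotyped])
        size_index = {int(v): i for i, v in enumerate(sizes)}
        idx = np.full_like(calls, -1)
        for (i, j), v in np.ndenumerate(calls):
            if genotyped[i]:
                idx[i, j] = size_index[int(v)]
        per_locus.append((idx, sizes.astype(float)))
    return per_locus, labels, samples


def unbiased_expected_heterozygosity(allele_counts) -> float:
    """Nei's unbiased expected heterozygosity from gene counts of one sample."""
    counts = np.asarray(allele_counts, dtype=float)
    counts = counts[counts > 0]
    ngenes = counts.sum()
    if ngenes < 2:
        return math.nan
    p = counts / ngenes
    return float(ngenes / (ngenes - 1.0) * (1.0 - np.sum(p**2)))


def rarefied_allelic_richness(allele_counts, g: int) -> float:
    """Expected number of distinct alleles in a subsample of ``g`` genes
    (hypergeometric rarefaction)."""
    counts = np.asarray(allele_counts, dtype=float)
    counts = counts[counts > 0]
    ngenes = counts.sum()
    if ngenes < g:
        return math.nan

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    total = 0.0
    for c in counts:
        if ngenes - c < g:
            total += 1.0
        else:
            total += 1.0 - math.exp(log_choose(ngenes - c, g) - log_choose(ngenes, g))
    return total


# ---------------------------------------------------------------------------
# Diversity


@dataclass
class LocusDiversity:
    """Per locus x population diversity measures and per-population means."""

    locus_ids: tuple[str, ...]
    populations: tuple[str, ...]
    n_genotyped: np.ndarray  # (nloci, npop)
    ho: np.ndarray
    he: np.ndarray
    k_alleles: np.ndarray
    allelic_richness: np.ndarray
    rarefaction_g: int

    def population_means(self) -> pd.DataFrame:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            return pd.DataFrame(
                {
                    "population": self.populations,
                    "n": np.nanmax(self.n_genotyped, axis=0).astype(int),
                    "Ho": np.nanmean(self.ho, axis=0),
                    "He": np.nanmean(self.he, axis=0),
                    "allelic_richness": np.nanmean(self.allelic_richness, axis=0),
                }
            )


def locus_diversity(gt: GenotypeTable, popmap: PopulationMap, g: int = 2) -> LocusDiversity:
    """Ho, unbiased He, allele counts, and rarefied allelic richness AR(g).

    The default rarefaction size g = 2 genes makes AR(g) = 1 + He exactly,
    the scale used in the source table. Empty population x locus cells are
    NaN.
    """
    per_locus, labels, _ = _locus_arrays(gt, popmap)
    nloci, npop = len(gt.locus_ids), len(popmap.populations)
    shape = (nloci, npop)
    n_gt = np.zeros(shape)
    ho = np.full(shape, np.nan)
    he = np.full(shape, np.nan)
    kmat = np.full(shape, np.nan)
    ar = np.full(shape, np.nan)
    for li, (idx, sizes) in enumerate(per_locus):
        genotyped = idx[:, 0] >= 0
        het = genotyped & (idx[:, 0] != idx[:, 1])
        for p in range(npop):
            mask = labels == p
            ng = int((genotyped & mask).sum())
            n_gt[li, p] = ng
            if ng == 0:
                continue
            counts = np.bincount(
                idx[mask & genotyped].ravel(), minlength=len(sizes)
            ).astype(float)
            ho[li, p] = (het & mask).sum() / ng
            he[li, p] = unbiased_expected_heterozygosity(counts) if ng >= 1 else np.nan
            kmat[li, p] = (counts > 0).sum()
            ar[li, p] = rarefied_allelic_richness(counts, g)
    return LocusDiversity(gt.locus_ids, popmap.populations, n_gt, ho, he, kmat, ar, g)


# ---------------------------------------------------------------------------
# Differentiation: GST family


def _gst_from_counts(freqs: np.ndarray, ns, hos) -> tuple:
    """Nei & Chesser bias-corrected (Hs, Ht, Ho_bar, k) from per-population
    allele frequencies, sample sizes (individuals), and observed Ho."""
    k = len(ns)
    if k < 2:
        return math.nan, math.nan, math.nan, k
    ns = np.asarray(ns, dtype=float)
    n_harm = k / np.sum(1.0 / ns)
    ho_bar = float(np.mean(hos))
    hs_plug = 1.0 - float(np.mean(np.sum(freqs**2, axis=1)))
    hs = n_harm / (n_harm - 1.0) * (hs_plug - ho_bar / (2.0 * n_harm))
    pbar = freqs.mean(axis=0)
    ht_plug = 1.0 - float(np.sum(pbar**2))
    ht = ht_plug + hs / (n_harm * k) - ho_bar / (2.0 * n_harm * k)
    return hs, ht, ho_bar, k


def _gst_components(idx: np.ndarray, labels: np.ndarray, pops) -> tuple:
    """Nei & Chesser bias-corrected (Hs, Ht, Ho_bar, k) for one locus.

    ``pops`` is the list of population codes to include; populations without
    genotyped individuals are skipped.
    """
    genotyped = idx[:, 0] >= 0
    n_alleles = int(idx.max()) + 1 if genotyped.any() else 0
    if n_alleles == 0:
        return math.nan, math.nan, math.nan, 0
    freqs = []
    ns = []
    hos = []
    for p in pops:
        mask = (labels == p) & genotyped
        n_p = int(mask.sum())
        if n_p == 0:
            continue
        counts = np.bincount(idx[mask].ravel(), minlength=n_alleles).astype(float)
        freqs.append(counts / counts.sum())
        ns.append(n_p)
        hos.append(float((idx[mask, 0] != idx[mask, 1]).mean()))
    if len(ns) < 2:
        return math.nan, math.nan, math.nan, len(ns)
    return _gst_from_counts(np.array(freqs), ns, hos)


def _combine(hs_list, ht_list, k: int) -> tuple:
    """Multilocus (FST, F'ST, D) by ratio of locus-averaged components."""
    hs = np.array(hs_list, dtype=float)
    ht = np.array(ht_list, dtype=float)
    ok = ~(np.isnan(hs) | np.isnan(ht))
    if not ok.any():
        return math.nan, math.nan, math.nan
    mhs, mht = float(hs[ok].mean()), float(ht[ok].mean())
    return _gst_family(mhs, mht, k)


def _gst_family(hs: float, ht: float, k: int) -> tuple:
    """(GST, Hedrick G'ST, Jost D) from Hs, Ht and the number of populations."""
    if not np.isfinite(hs) or not np.isfinite(ht) or ht <= 0 or k < 2:
        return math.nan, math.nan, math.nan
    gst = (ht - hs) / ht
    if hs >= 1.0:
        return gst, math.nan, math.nan
    gst_std = gst * (k - 1.0 + hs) / ((k - 1.0) * (1.0 - hs))
    jost_d = (ht - hs) / (1.0 - hs) * k / (k - 1.0)
    return gst, gst_std, jost_d


@dataclass
class DifferentiationResult:
    locus_ids: tuple[str, ...]
    populations: tuple[str, ...]
    per_locus: pd.DataFrame  # columns locus, FST, FpST, D
    fst: float
    fst_std: float
    jost_d: float
    overall_p: float
    pairwise_fst: np.ndarray
    pairwise_fst_std: np.ndarray
    pairwise_d: np.ndarray
    pairwise_p_fst: np.ndarray
    pairwise_p_fst_std: np.ndarray
    fdr_flags_fst: np.ndarray
    fdr_flags_fst_std: np.ndarray
    fdr_critical: float


def _multilocus_stats(per_locus, labels, pops) -> tuple:
    hs_list, ht_list = [], []
    kmax = 2
    for idx, _sizes in per_locus:
        hs, ht, _, k = _gst_components(idx, labels, pops)
        if k >= 2 and np.isfinite(hs) and np.isfinite(ht):
            hs_list.append(hs)
            ht_list.append(ht)
            kmax = max(kmax, k)
    if not hs_list:
        return math.nan, math.nan, math.nan
    return _combine(hs_list, ht_list, kmax)


def differentiation(
    gt: GenotypeTable,
    popmap: PopulationMap,
    n_perm: int = 10000,
    rng_seed: int = 0,
) -> DifferentiationResult:
    """Per-locus and multilocus FST (bias-corrected GST), Hedrick's F'ST,
    and Jost's D, overall and pairwise, with permutation p-values.

    Monomorphic loci contribute 0 differentiation and are flagged by NaN in
    the per-locus table. FDR flags (Benjamini-Yekutieli) are computed over
    the pooled pairwise FST + F'ST p-values, matching reporting practice.
    """
    if len(popmap.populations) < 2:
        raise ValueError("differentiation needs at least 2 populations")
    per_locus, labels, _ = _locus_arrays(gt, popmap)
    npop = len(popmap.populations)
    all_pops = list(range(npop))
    rng = np.random.default_rng(rng_seed)

    rows = []
    for li, (idx, _) in enumerate(per_locus):
        hs, ht, _, k = _gst_components(idx, labels, all_pops)
        gst, gstd, d = _gst_family(hs, ht, k)
        rows.append({"locus": gt.locus_ids[li], "FST": gst, "FpST": gstd, "D": d})
    per_locus_df = pd.DataFrame(rows)

    fst, fst_std, jost_d = _multilocus_stats(per_locus, labels, all_pops)

    # overall permutation p on multilocus FST
    count = 0
    lab = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(lab)
        f, _, _ = _multilocus_stats(per_locus, lab, all_pops)
        if np.isfinite(f) and f >= fst - 1e-12:
            count += 1
    overall_p = (count + 1) / (n_perm + 1)

    shape = (npop, npop)
    pw_fst = np.full(shape, np.nan)
    pw_fst_std = np.full(shape, np.nan)
    pw_d = np.full(shape, np.nan)
    pw_p_fst = np.full(shape, np.nan)
    pw_p_fstd = np.full(shape, np.nan)
    pair_rng = np.random.default_rng([0 if rng_seed is None else rng_seed, 7])
    for a in range(npop):
        for b in range(a + 1, npop):
            sel = np.flatnonzero((labels == a) | (labels == b))
            sub_labels = labels[sel]
            sub_locus = [(idx[sel], sizes) for idx, sizes in per_locus]
            f, fs, d = _multilocus_stats(sub_locus, sub_labels, [a, b])
            pw_fst[a, b] = pw_fst[b, a] = f
            pw_fst_std[a, b] = pw_fst_std[b, a] = fs
            pw_d[a, b] = pw_d[b, a] = d
            cf = cfs = 0
            lab2 = sub_labels.copy()
            for _ in range(n_perm):
                pair_rng.shuffle(lab2)
                pf, pfs, _ = _multilocus_stats(sub_locus, lab2, [a, b])
                if np.isfinite(pf) and pf >= f - 1e-12:
                    cf += 1
                if np.isfinite(pfs) and np.isfinite(fs) and pfs >= fs - 1e-12:
                    cfs += 1
            pw_p_fst[a, b] = pw_p_fst[b, a] = (cf + 1) / (n_perm + 1)
            pw_p_fstd[a, b] = pw_p_fstd[b, a] = (cfs + 1) / (n_perm + 1)

    iu = np.triu_indices(npop, k=1)
    pooled = np.concatenate([pw_p_fst[iu], pw_p_fstd[iu]])
    valid = ~np.isnan(pooled)
    flags_pool = np.zeros(pooled.size, dtype=bool)
    critical = math.nan
    if valid.any():
        fl, critical = fdr_correct(pooled[valid].tolist(), alpha=0.05)
        flags_pool[valid] = fl
    npairs = len(iu[0])
    flags_fst = np.zeros(shape, dtype=bool)
    flags_fstd = np.zeros(shape, dtype=bool)
    flags_fst[iu] = flags_pool[:npairs]
    flags_fstd[iu] = flags_pool[npairs:]
    flags_fst |= flags_fst.T
    flags_fstd |= flags_fstd.T

    return DifferentiationResult(
        locus_ids=gt.locus_ids,
        populations=popmap.populations,
        per_locus=per_locus_df,
        fst=fst,
        fst_std=fst_std,
        jost_d=jost_d,
        overall_p=overall_p,
        pairwise_fst=pw_fst,
        pairwise_fst_std=pw_fst_std,
        pairwise_d=pw_d,
        pairwise_p_fst=pw_p_fst,
        pairwise_p_fst_std=pw_p_fstd,
        fdr_flags_fst=flags_fst,
        fdr_flags_fst_std=flags_fstd,
        fdr_critical=critical,
    )


# ---------------------------------------------------------------------------
# Goldstein's (delta-mu)^2


@dataclass
class DeltaMuResult:
    populations: tuple[str, ...]
    matrix: np.ndarray  # (npop, npop), mean over loci of squared mean-size difference


def delta_mu_squared(gt: GenotypeTable, popmap: PopulationMap) -> DeltaMuResult:
    """Goldstein's (delta-mu)^2: squared difference of mean allele size per
    locus, averaged over loci shared by each population pair."""
    per_locus, labels, _ = _locus_arrays(gt, popmap)
    npop = len(popmap.populations)
    nloci = len(per_locus)
    means = np.full((nloci, npop), np.nan)
    for li, (idx, sizes) in enumerate(per_locus):
        genotyped = idx[:, 0] >= 0
        for p in range(npop):
            mask = (labels == p) & genotyped
            if mask.any():
                means[li, p] = sizes[idx[mask].ravel()].mean()
    out = np.zeros((npop, npop))
    for a in range(npop):
        for b in range(a + 1, npop):
            diffs = (means[:, a] - means[:, b]) ** 2
            ok = ~np.isnan(diffs)
            val = float(diffs[ok].mean()) if ok.any() else math.nan
            out[a, b] = out[b, a] = val
    return DeltaMuResult(popmap.populations, out)


# ---------------------------------------------------------------------------
# Bottleneck heterozygosity-excess test


@dataclass
class BottleneckResult:
    population: str
    model: str
    per_locus: pd.DataFrame  # locus, n_genes, k, He, Heq_mean, Heq_sd, std_diff
    wilcoxon_p_excess: float
    n_loci_used: int
    low_power: bool


def _sim_equilibrium_locus(
    n_genes: int, theta: float, model: str, p_single: float, geom_q: float, rng
) -> tuple[int, float]:
    """One neutral coalescent + mutation replicate: (allele count, unbiased He)."""
    g = n_genes
    masks = [1 << i for i in range(g)]
    birth = [0.0] * g
    t = 0.0
    branches: list = []
    exp_draws = rng.exponential(size=g - 1)
    for step in range(g - 1):
        k = len(masks)
        t += exp_draws[step] * 2.0 / (k * (k - 1))
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        if i > j:
            i, j = j, i
        branches.append((masks[i], t - birth[i]))
        branches.append((masks[j], t - birth[j]))
        masks[i] |= masks[j]
        birth[i] = t
        del masks[j], birth[j]
    lens = np.array([b[1] for b in branches])
    total = float(lens.sum())
    n_mut = rng.poisson(theta / 2.0 * total)
    if n_mut == 0:
        return 1, 0.0
    which = rng.choice(len(branches), size=n_mut, p=lens / total)
    if model == "IAM":
        sigs = [0] * g
        for m_idx, b_idx in enumerate(which):
            mask = branches[b_idx][0]
            for s in range(g):
                if (mask >> s) & 1:
                    sigs[s] |= 1 << m_idx
        values = sigs
    else:
        steps = np.ones(n_mut)
        if model == "TPM" and p_single < 1.0:
            multi = rng.random(n_mut) >= p_single
            if multi.any():
                steps[multi] = rng.geometric(geom_q, size=int(multi.sum()))
        steps *= rng.choice([-1.0, 1.0], size=n_mut)
        vals = np.zeros(g)
        for m_idx, b_idx in enumerate(which):
            mask = branches[b_idx][0]
            delta = steps[m_idx]
            for s in range(g):
                if (mask >> s) & 1:
                    vals[s] += delta
        values = vals.tolist()
    counts = np.array(list(Counter(values).values()), dtype=float)
    p = counts / g
    he = g / (g - 1.0) * (1.0 - float(np.sum(p**2)))
    return len(counts), he


def _theta_from_k(n_genes: int, k_obs: int) -> float:
    """theta with Ewens expectation E[K] = k_obs (exact for IAM; a usable
    starting point for stepwise models, refined adaptively)."""
    lo, hi = 1e-4, 1e4
    for _ in range(60):
        mid = math.sqrt(lo * hi)
        ek = sum(mid / (mid + i) for i in range(n_genes))
        if ek < k_obs:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def _conditional_heq(
    n_genes: int, k_obs: int, model: str, p_single: float, geom_q: float,
    n_sim: int, rng,
) -> np.ndarray:
    """Heq draws conditional on the observed allele count, by rejection.

    theta starts at the Ewens-matched value and is rescaled adaptively when
    the simulated allele counts drift away from k_obs (stepwise models
    produce fewer alleles per mutation than IAM).
    """
    theta = _theta_from_k(n_genes, k_obs)
    if model != "IAM":
        # stepwise homoplasy: same theta yields fewer observed alleles, so
        # recalibrate on pilot simulations until mean k matches k_obs
        for _round in range(3):
            ks = [
                _sim_equilibrium_locus(n_genes, theta, model, p_single, geom_q, rng)[0]
                for _ in range(40)
            ]
            mean_k = float(np.mean(ks))
            if abs(mean_k - k_obs) < 0.15:
                break
            theta *= (k_obs - 1.0) / max(mean_k - 1.0, 0.25)
    out: list = []
    attempts = 0
    cap = 40 * n_sim
    while len(out) < n_sim and attempts < cap:
        k_sim, he = _sim_equilibrium_locus(n_genes, theta, model, p_single, geom_q, rng)
        attempts += 1
        if k_sim == k_obs:
            out.append(he)
    return np.array(out)


def bottleneck_test(
    gt: GenotypeTable,
    popmap: PopulationMap,
    model: str = "TPM",
    tpm_single_prop: float = 0.9,
    tpm_variance_prop: float = 0.36,
    n_sim: int = 1000,
    rng_seed: int = 0,
) -> dict:
    """Heterozygosity-excess bottleneck test, per population.

    For each polymorphic locus, equilibrium Heq is the distribution of
    unbiased He over ``n_sim`` coalescent simulations of the same number of
    genes, conditioned on the observed allele count k: theta is tuned so the
    expected allele count matches k (Ewens closed form, refined by pilot
    simulation for stepwise models), then replicates are rejected unless
    k_sim = k. A one-tailed Wilcoxon signed-rank across loci on the
    conditional quantiles of He (symmetric about 0.5 at equilibrium) tests
    for heterozygosity excess.

    ``tpm_variance_prop`` sets the variance of the geometric multi-step
    component of the TPM; the geometric parameter q solves
    (1-q)/q^2 = variance.
    """
    if model not in ("IAM", "SMM", "TPM"):
        raise ValueError(f"unknown mutation model {model!r}")
    v = max(tpm_variance_prop, 1e-6)
    geom_q = (-1.0 + math.sqrt(1.0 + 4.0 * v)) / (2.0 * v)
    geom_q = min(max(geom_q, 1e-6), 1.0)
    per_locus, labels, _ = _locus_arrays(gt, popmap)
    results: dict = {}
    for p, pop in enumerate(popmap.populations):
        rng = np.random.default_rng([0 if rng_seed is None else rng_seed, p])
        rows = []
        for li, (idx, _sizes) in enumerate(per_locus):
            mask = (labels == p) & (idx[:, 0] >= 0)
            ng = int(mask.sum())
            if ng < 2:
                continue
            counts = np.bincount(idx[mask].ravel()).astype(float)
            counts = counts[counts > 0]
            k_obs = len(counts)
            if k_obs < 2:
                continue
            n_genes = 2 * ng
            he_obs = unbiased_expected_heterozygosity(counts)
            heqs = _conditional_heq(
                n_genes, k_obs, model, tpm_single_prop, geom_q, n_sim, rng
            )
            if len(heqs) < max(10, n_sim // 10):
                warnings.warn(
                    f"locus {gt.locus_ids[li]} pop {pop}: only {len(heqs)} "
                    f"conditional replicates; Heq estimate is noisy"
                )
            if len(heqs) < 2:
                continue
            heq_mean, heq_sd = float(heqs.mean()), float(heqs.std(ddof=1))
            std_diff = (he_obs - heq_mean) / heq_sd if heq_sd > 0 else math.nan
            # mid-quantile of He within the conditional Heq distribution:
            # uniform under equilibrium, near 1 under heterozygosity excess
            quant = (
                float((heqs < he_obs).sum()) + 0.5 * float((heqs == he_obs).sum()) + 0.5
            ) / (len(heqs) + 1.0)
            rows.append(
                {
                    "locus": gt.locus_ids[li],
                    "n_genes": n_genes,
                    "k": k_obs,
                    "He": he_obs,
                    "Heq_mean": heq_mean,
                    "Heq_sd": heq_sd,
                    "std_diff": std_diff,
                    "quantile": quant,
                }
            )
        df = pd.DataFrame(rows)
        if len(df) >= 2 and not np.allclose(df["quantile"], 0.5):
            # signed-rank on the conditional quantile residuals: symmetric
            # about 0 under equilibrium, hence a calibrated excess test
            stat_p = wilcoxon(
                df["quantile"] - 0.5, alternative="greater", zero_method="wilcox"
            ).pvalue
        else:
            stat_p = math.nan
        results[pop] = BottleneckResult(
            population=pop,
            model=model,
            per_locus=df,
            wilcoxon_p_excess=float(stat_p),
            n_loci_used=len(df),
            low_power=len(df) < 4,
        )
    return results


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class Ordination:
    ids: tuple[str, ...]
    coordinates: np.ndarray  # (n, n_axes), axes from positive eigenvalues
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives reported)
    proportion_explained: np.ndarray  # over positive eigenvalues


def pcoa(dist: np.ndarray, ids=None, n_axes: int | None = None) -> Ordination:
    """Classical multidimensional scaling of a distance matrix.

    Distances are squared, double-centered, and eigendecomposed; axes are
    built from positive eigenvalues only, negative eigenvalues are reported.
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > max(1e-12, 1e-10 * abs(vals).max() if vals.size else 0)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    if n_axes is not None:
        coords = coords[:, :n_axes]
    prop = vals[pos] / vals[pos].sum() if pos.any() else np.array([])
    if ids is None:
        ids = tuple(str(i) for i in range(n))
    return Ordination(tuple(ids), coords, vals, prop)
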