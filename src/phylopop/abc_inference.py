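"""ABC scenario choice with the direct (k-nearest-neighbour) estimator.

The summary-statistic set follows the study design: per population the mtDNA
Tajima's D, mtDNA mean pairwise differences, and microsatellite mean genic
diversity; per population pair the mtDNA FST (pairwise-difference AMOVA),
microsatellite FST, and Goldstein's (delta-mu)^2. Statistics are MAD-scaled
before Euclidean distance computation, the posterior probability of a
scenario is its frequency among the k nearest reference rows, and confidence
is evaluated by classifying held-out (or freshly simulated) pseudo-observed
datasets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from phylopop.coalescent_sim import (
    StudyConfig,
    SyntheticDataset,
    make_synthetic_study,
)
from phylopop.mtdna_stats import tajima_d, _amova_phi
from phylopop.msat_stats import _locus_arrays, _gst_from_counts, _gst_family

__all__ = [
    "SummaryStatsVector",
    "ReferenceTable",
    "ModelChoiceResult",
    "ConfidenceResult",
    "compute_summary_stats",
    "build_reference_table",
    "direct_posterior",
    "scenario_confidence",
]


@dataclass(frozen=True)
class SummaryStatsVector:
    """Fixed, ordered statistic vector; labels are stable across datasets."""

    labels: tuple
    values: np.ndarray

    def marker_mask(self, marker: str) -> np.ndarray:
        """Boolean mask of components for one marker ('mt' or 'msat')."""
        return np.array([lab.startswith(marker + ":") for lab in self.labels])


def _variable_columns(codes: np.ndarray) -> np.ndarray:
    cmax = codes.max(axis=0)
    cmin = codes.min(axis=0)
    return np.flatnonzero(cmax != cmin)


def compute_summary_stats(ds: SyntheticDataset) -> SummaryStatsVector:
    """Summary-statistic vector for one (synthetic or observed) dataset.

    Delegates to the statistic implementations in :mod:`phylopop.mtdna_stats`
    and :mod:`phylopop.msat_stats` with fixed settings; deterministic given
    the data. Missing components (e.g. an undefined pairwise statistic) are
    imputed as 0.
    """
    pops = list(ds.aln_popmap.populations)
    labels: list = []
    values: list = []

    # --- mtDNA: restrict to variable columns, complete-data fast path
    codes = ds.mt_codes if getattr(ds, "mt_codes", None) is not None else ds.alignment.to_codes()
    index = {sid: i for i, sid in enumerate(ds.alignment.sample_ids)}
    var = _variable_columns(codes)
    sub = codes[:, var] if len(var) else codes[:, :0]
    diff = (sub[:, None, :] != sub[None, :, :]).sum(axis=2).astype(float)
    pop_rows = {p: np.array([index[s] for s in ds.aln_popmap.samples_in(p)]) for p in pops}

    mt_d = {}
    mt_pi = {}
    for p in pops:
        rows = pop_rows[p]
        n = len(rows)
        block = sub[rows]
        S = len(_variable_columns(block)) if n else 0
        dmat = diff[np.ix_(rows, rows)]
        pi_tot = float(dmat[np.triu_indices(n, 1)].mean()) if n >= 2 else 0.0
        mt_d[p] = tajima_d(S, pi_tot, n)
        mt_pi[p] = pi_tot

    # --- microsatellites: per locus x population counts computed once
    per_locus, labels_arr, _ = _locus_arrays(ds.genotypes, ds.gt_popmap)
    msat_pops = list(ds.gt_popmap.populations)
    npop_ms = len(msat_pops)
    loc_freqs: list = []  # per locus: (npop, n_alleles) frequencies or None rows
    loc_ns: list = []
    loc_hos: list = []
    gen_div = {p: [] for p in msat_pops}
    for idx, _sizes in per_locus:
        genotyped = idx[:, 0] >= 0
        n_alleles = int(idx.max()) + 1 if genotyped.any() else 0
        freqs = np.zeros((npop_ms, max(n_alleles, 1)))
        ns = np.zeros(npop_ms)
        hos = np.zeros(npop_ms)
        for pi_ in range(npop_ms):
            mask = (labels_arr == pi_) & genotyped
            n_p = int(mask.sum())
            ns[pi_] = n_p
            if n_p == 0:
                continue
            counts = np.bincount(idx[mask].ravel(), minlength=max(n_alleles, 1)).astype(float)
            freqs[pi_] = counts / counts.sum()
            hos[pi_] = float((idx[mask, 0] != idx[mask, 1]).mean())
            ngenes = 2.0 * n_p
            he = ngenes / (ngenes - 1.0) * (1.0 - float(np.sum(freqs[pi_] ** 2)))
            gen_div[msat_pops[pi_]].append(he)
        loc_freqs.append(freqs)
        loc_ns.append(ns)
        loc_hos.append(hos)
    gen_div = {p: (float(np.mean(v)) if v else 0.0) for p, v in gen_div.items()}

    for p in pops:
        labels.append(f"mt:D:{p}")
        values.append(mt_d[p])
        labels.append(f"mt:pi:{p}")
        values.append(mt_pi[p])
        labels.append(f"msat:He:{p}")
        values.append(gen_div.get(p, 0.0))

    # --- pairwise components
    mean_sizes = np.full((len(per_locus), len(msat_pops)), np.nan)
    for li, (idx, sizes) in enumerate(per_locus):
        genotyped = idx[:, 0] >= 0
        for pi_ in range(len(msat_pops)):
            mask = (labels_arr == pi_) & genotyped
            if mask.any():
                mean_sizes[li, pi_] = sizes[idx[mask].ravel()].mean()

    for a in range(len(pops)):
        for b in range(a + 1, len(pops)):
            pa, pb = pops[a], pops[b]
            rows = np.concatenate([pop_rows[pa], pop_rows[pb]])
            grp = np.array([0] * len(pop_rows[pa]) + [1] * len(pop_rows[pb]))
            phi = _amova_phi(diff[np.ix_(rows, rows)], grp, 2)
            labels.append(f"mt:FST:{pa}|{pb}")
            values.append(phi if math.isfinite(phi) else 0.0)

            hs_list, ht_list = [], []
            for freqs, ns, hos in zip(loc_freqs, loc_ns, loc_hos):
                if ns[a] == 0 or ns[b] == 0:
                    continue
                hs, ht, _, kk = _gst_from_counts(
                    freqs[[a, b]], ns[[a, b]], hos[[a, b]]
                )
                if kk >= 2 and np.isfinite(hs) and np.isfinite(ht):
                    hs_list.append(hs)
                    ht_list.append(ht)
            if hs_list:
                fst, _, _ = _gst_family(float(np.mean(hs_list)), float(np.mean(ht_list)), 2)
            else:
                fst = 0.0
            labels.append(f"msat:FST:{pa}|{pb}")
            values.append(fst if math.isfinite(fst) else 0.0)

            dmu = (mean_sizes[:, a] - mean_sizes[:, b]) ** 2
            ok = ~np.isnan(dmu)
            labels.append(f"msat:dmu2:{pa}|{pb}")
            values.append(float(dmu[ok].mean()) if ok.any() else 0.0)

    return SummaryStatsVector(tuple(labels), np.array(values, dtype=float))


# ---------------------------------------------------------------------------
# Reference table


@dataclass
class ReferenceTable:
    scenario_ids: np.ndarray  # (n_rows,) of str
    stats: np.ndarray  # (n_rows, n_stats)
    labels: tuple
    scales: np.ndarray  # per-statistic robust scale, strictly positive
    scenarios: tuple  # distinct scenario ids, fixed order
    seeds: np.ndarray | None = None

    @property
    def n_rows(self) -> int:
        return len(self.scenario_ids)

    def to_tsv(self, path, metadata_path=None) -> None:
        df = pd.DataFrame(self.stats, columns=list(self.labels))
        df.insert(0, "scenario", self.scenario_ids)
        df.to_csv(path, sep="\t", index=False)
        if metadata_path:
            with open(metadata_path, "w") as fh:
                json.dump(
                    {
                        "scenarios": list(self.scenarios),
                        "labels": list(self.labels),
                        "scales": self.scales.tolist(),
                    },
                    fh,
                    indent=1,
                )

    @classmethod
    def from_tsv(cls, path) -> "ReferenceTable":
        df = pd.read_csv(path, sep="\t")
        labels = tuple(df.columns[1:])
        stats = df.iloc[:, 1:].to_numpy(dtype=float)
        scen = df["scenario"].to_numpy(dtype=str)
        order = list(dict.fromkeys(scen))
        return cls(scen, stats, labels, _mad_scales(stats), tuple(order))


def _mad_scales(stats: np.ndarray) -> np.ndarray:
    """Median absolute deviation per column; fallback SD, then 1."""
    med = np.median(stats, axis=0)
    mad = np.median(np.abs(stats - med), axis=0)
    sd = stats.std(axis=0)
    scales = np.where(mad > 0, mad, np.where(sd > 0, sd, 1.0))
    return scales


def build_reference_table(
    scenarios,
    n_per_scenario: int,
    rng_seed: int = 0,
    config: StudyConfig | None = None,
) -> ReferenceTable:
    """Simulate ``n_per_scenario`` datasets per scenario and summarize them.

    Rows are generated scenario-by-scenario with per-row seeds derived from
    ``rng_seed``, so a fixed seed yields an identical table.
    """
    scenarios = tuple(scenarios)
    rng = np.random.default_rng(rng_seed)
    rows = []
    ids = []
    seeds = []
    labels = None
    for scen in scenarios:
        for _ in range(n_per_scenario):
            seed = int(rng.integers(2**31 - 1))
            ds = make_synthetic_study(scen, seed, config)
            vec = compute_summary_stats(ds)
            if labels is None:
                labels = vec.labels
            rows.append(vec.values)
            ids.append(scen)
            seeds.append(seed)
    stats = np.array(rows)
    return ReferenceTable(
        np.array(ids), stats, labels, _mad_scales(stats), scenarios, np.array(seeds)
    )


# ---------------------------------------------------------------------------
# Direct-approach model choice


@dataclass
class ModelChoiceResult:
    posterior: dict  # scenario -> probability
    k: int
    kth_distance: float
    neighbor_indices: np.ndarray


def _scaled_distances(
    observed: np.ndarray, table: ReferenceTable, mask: np.ndarray | None
) -> np.ndarray:
    obs = observed / table.scales
    ref = table.stats / table.scales
    if mask is not None:
        obs = obs[mask]
        ref = ref[:, mask]
    return np.sqrt(((ref - obs) ** 2).sum(axis=1))


def direct_posterior(
    observed: SummaryStatsVector,
    table: ReferenceTable,
    k: int = 500,
    marker: str | None = None,
    exclude_row: int | None = None,
) -> ModelChoiceResult:
    """Posterior scenario probabilities from the k nearest reference rows.

    Euclidean distance on MAD-scaled statistics; ties at the k-th distance
    are broken by stable row order. ``marker`` restricts the statistic set to
    one marker type ('mt' or 'msat').
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > table.n_rows - (1 if exclude_row is not None else 0):
        raise ValueError("k exceeds the number of usable reference rows")
    mask = observed.marker_mask(marker) if marker else None
    d = _scaled_distances(observed.values, table, mask)
    if exclude_row is not None:
        d[exclude_row] = np.inf
    nearest = np.argsort(d, kind="stable")[:k]
    posterior = {
        scen: float((table.scenario_ids[nearest] == scen).mean())
        for scen in table.scenarios
    }
    return ModelChoiceResult(posterior, k, float(d[nearest[-1]]), nearest)


# ---------------------------------------------------------------------------
# Confidence evaluation


@dataclass
class ConfidenceResult:
    scenarios: tuple
    confusion: np.ndarray  # (true, chosen) classification counts
    misclassification: dict  # scenario -> error rate
    overall_error: float


def scenario_confidence(
    table: ReferenceTable,
    k: int = 500,
    n_pods: int = 500,
    rng_seed: int = 0,
    fresh: bool = False,
    config: StudyConfig | None = None,
    marker: str | None = None,
) -> ConfidenceResult:
    """Misclassification rates from pseudo-observed datasets (PODs).

    By default PODs are held-out reference rows (leave-one-out): each sampled
    row is classified against the table with itself excluded. With
    ``fresh=True``, new datasets are simulated instead (slower, no reuse).
    """
    if table.n_rows <= k:
        raise ValueError("reference table too small for the requested k")
    if n_pods < 1:
        raise ValueError("n_pods must be >= 1")
    rng = np.random.default_rng(rng_seed)
    scen_index = {s: i for i, s in enumerate(table.scenarios)}
    nsc = len(table.scenarios)
    confusion = np.zeros((nsc, nsc), dtype=int)
    per_scen = max(1, n_pods // nsc)
    for scen in table.scenarios:
        if fresh:
            for _ in range(per_scen):
                seed = int(rng.integers(2**31 - 1))
                ds = make_synthetic_study(scen, seed, config)
                vec = compute_summary_stats(ds)
                res = direct_posterior(vec, table, k, marker=marker)
                chosen = max(res.posterior, key=res.posterior.get)
                confusion[scen_index[scen], scen_index[chosen]] += 1
        else:
            rows = np.flatnonzero(table.scenario_ids == scen)
            picks = rng.choice(rows, size=per_scen, replace=len(rows) < per_scen)
            for row in picks:
                vec = SummaryStatsVector(table.labels, table.stats[row])
                res = direct_posterior(vec, table, k, marker=marker, exclude_row=int(row))
                chosen = max(res.posterior, key=res.posterior.get)
                confusion[scen_index[scen], scen_index[chosen]] += 1
    totals = confusion.sum(axis=1)
    mis = {
        s: float(1.0 - confusion[i, i] / totals[i]) if totals[i] else math.nan
        for s, i in scen_index.items()
    }
    overall = float(1.0 - np.trace(confusion) / confusion.sum())
    return ConfidenceResult(table.scenarios, confusion, mis, overall)
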