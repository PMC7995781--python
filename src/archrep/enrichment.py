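"""Monte Carlo enrichment/depletion of repeat density in gene sets.

For each (family, region, orientation) stratum, the observed mean density
of a target gene set is compared with a null distribution of means obtained
by repeatedly drawing, without replacement, background subsets of the same
size.  The standardized deviation is the enrichment Z-score: positive means
denser than expected by chance, negative means sparser.  An empirical
two-sided p-value from the same resamples feeds Benjamini-Hochberg FDR
across all strata of the comparison; a Kolmogorov-Smirnov test of the
per-gene density distributions is reported alongside.  A stratum is called
significant when |Z| >= z_threshold and FDR <= fdr_threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["MCConfig", "bh_fdr", "MonteCarloEnrichment", "MonteCarloEnrichmentResults"]


@dataclass
class MCConfig:
    """Parameters of the resampling null.

    iterations : number of background resamples (default 10,000)
    z_threshold : |Z| needed to call enrichment/depletion (default 2)
    fdr_threshold : BH-FDR cutoff (default 5%)
    """

    iterations: int = 10_000
    seed: int = 0
    z_threshold: float = 2.0
    fdr_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.iterations < 100:
            raise ValueError("iterations must be >= 100")
        if self.z_threshold <= 0 or self.fdr_threshold <= 0:
            raise ValueError("thresholds must be positive")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


class MonteCarloEnrichment:
    """Resampling enrichment model for one target-vs-background comparison.

    Parameters
    ----------
    densities : DataFrame
        Long-format density table with columns gene_id, family, region,
        orientation, density (as produced by
        :func:`archrep.repeats.density_table`).
    target, background : iterable of str
        Gene ids; target must be a subset of background and strictly
        smaller, and every gene must appear in ``densities``.
    config : MCConfig, optional
    """

    def __init__(self, densities: pd.DataFrame, target, background, config: MCConfig | None = None):
        self.config = config or MCConfig()
        target = sorted(set(target))
        background = sorted(set(background))
        if not set(target) <= set(background):
            raise ValueError("target gene set must be a subset of the background")
        if not len(background) > len(target) > 0:
            raise ValueError("background must be strictly larger than the non-empty target")
        known = set(densities["gene_id"].unique())
        missing = set(background) - known
        if missing:
            raise ValueError(f"genes without density records: {sorted(missing)[:5]} ...")
        self.target = target
        self.background = background
        # genes x strata matrix; NaN where a gene has no record (e.g. no intron)
        wide = densities.pivot_table(
            index="gene_id",
            columns=["family", "region", "orientation"],
            values="density",
            aggfunc="first",
        )
        self._matrix = wide.reindex(background)
        self._strata = list(wide.columns)

    def fit(self, seed: int | None = None) -> "MonteCarloEnrichmentResults":
        """Run the Monte Carlo resampling; deterministic for a given seed."""
        cfg = self.config
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
        n_bg = len(self.background)
        n_target = len(self.target)
        # one shared set of resampled gene subsets across all strata, as in
        # per-iteration "random choice of genes" from the background
        idx = np.empty((cfg.iterations, n_target), dtype=np.int64)
        for i in range(cfg.iterations):
            idx[i] = rng.choice(n_bg, size=n_target, replace=False)

        values = self._matrix.to_numpy(dtype=float)
        target_pos = self._matrix.index.get_indexer(self.target)
        rows = []
        for j, (family, region, orientation) in enumerate(self._strata):
            col = values[:, j]
            target_vals = col[target_pos]
            target_vals = target_vals[~np.isnan(target_vals)]
            bg_vals = col[~np.isnan(col)]
            observed = float(np.mean(target_vals)) if target_vals.size else np.nan
            with np.errstate(invalid="ignore"):
                null_means = np.nanmean(col[idx], axis=1)
            null_means = null_means[~np.isnan(null_means)]
            expected = float(np.mean(null_means))
            sd = float(np.std(null_means, ddof=1))
            if sd > 0 and np.isfinite(observed):
                z = (observed - expected) / sd
                lo = (1 + np.sum(null_means <= observed)) / (1 + len(null_means))
                hi = (1 + np.sum(null_means >= observed)) / (1 + len(null_means))
                mc_p = min(1.0, 2.0 * min(lo, hi))
                evaluable = True
            else:
                z, mc_p, evaluable = np.nan, np.nan, False
            if target_vals.size >= 1 and bg_vals.size >= 1 and (
                np.ptp(bg_vals) > 0 or np.ptp(target_vals) > 0
            ):
                ks_stat, ks_p = stats.ks_2samp(target_vals, bg_vals)
            else:
                ks_stat, ks_p = 0.0, 1.0
            rows.append(
                {
                    "family": family,
                    "region": region,
                    "orientation": orientation,
                    "n_target": int(target_vals.size),
                    "observed_mean": observed,
                    "expected_mean": expected,
                    "expected_sd": sd,
                    "z": z,
                    "mc_p": mc_p,
                    "ks_stat": float(ks_stat),
                    "ks_p": float(ks_p),
                    "evaluable": evaluable,
                }
            )
        table = pd.DataFrame(rows)
        table["fdr"] = np.nan
        table["fdr_ks"] = np.nan
        mask = table["evaluable"].to_numpy()
        if mask.any():
            table.loc[mask, "fdr"] = bh_fdr(table.loc[mask, "mc_p"])
            table.loc[mask, "fdr_ks"] = bh_fdr(table.loc[mask, "ks_p"])
        table["significant"] = (
            mask
            & (table["z"].abs() >= cfg.z_threshold)
            & (table["fdr"] <= cfg.fdr_threshold)
        )
        return MonteCarloEnrichmentResults(
            table=table,
            config=cfg,
            seed=cfg.seed if seed is None else seed,
            n_target=n_target,
            n_background=n_bg,
        )


@dataclass
class MonteCarloEnrichmentResults:
    """Fitted enrichment table plus reporting helpers."""

    table: pd.DataFrame
    config: MCConfig
    seed: int
    n_target: int
    n_background: int

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]

    def heatmap_matrix(self) -> pd.DataFrame:
        """Z-score matrix, families x (region, orientation).

        Only families with at least one |Z| above the threshold are kept;
        non-evaluable cells are missing (NaN).
        """
        t = self.table
        wide = t.pivot_table(
            index="family", columns=["region", "orientation"], values="z", aggfunc="first"
        )
        keep = wide.index[(wide.abs() >= self.config.z_threshold).any(axis=1).to_numpy()]
        return wide.loc[keep]

    def summary(self) -> str:
        lines = [
            "Monte Carlo repeat-density enrichment",
            f"  target genes:      {self.n_target}",
            f"  background genes:  {self.n_background}",
            f"  iterations:        {self.config.iterations}",
            f"  seed:              {self.seed}",
            f"  call rule:         |Z| >= {self.config.z_threshold}, "
            f"FDR <= {self.config.fdr_threshold}",
            "",
        ]
        cols = ["family", "region", "orientation", "observed_mean", "z", "fdr", "significant"]
        lines.append(self.table[cols].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)
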