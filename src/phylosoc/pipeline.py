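"""End-to-end analysis: metrics, per-taxon and pooled regressions, exports.

The orchestration mirrors the comparative workflow: per-species metrics
and the taxon summary are computed for every record, but only species
with multiple breeding females enter the regressions (with a single
breeder there is, by definition, no variation in breeder number to
model).  Each taxon is fitted against its own tree-derived correlation
matrix; when several candidate trees are supplied for a taxon the fit
is repeated per tree and parameter estimates averaged.  The pooled
across-taxa model uses taxonomic class as a random intercept, since no
single phylogeny spans all four groups.  Everything is deterministic
given the run seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import Dataset, read_species_table
from .metrics import MULTI_BREEDER, compute_metrics, taxon_summary
from .regression import (
    ChainConfig,
    PhylogeneticGLS,
    RegressionFit,
    mixed_mcmc,
)
from .trees import correlation_from_tree, prune_to_taxa, read_newick, tip_labels

logger = logging.getLogger("phylosoc")

__all__ = ["AnalysisConfig", "ResultsBundle", "run_analysis", "export_figure_tables"]


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run."""

    trait_table: str
    trees: dict[str, list[str]] = field(default_factory=dict)
    treeless_taxa: tuple[str, ...] = ()
    transform: str = "log"
    log_base: str = "natural"
    chain: ChainConfig = field(default_factory=ChainConfig)
    out_dir: str | None = None
    seed: int = 0
    min_multibreeder: int = 3

    def __post_init__(self) -> None:
        if self.transform not in ("log", "logit", "identity"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.log_base not in ("natural", "base10"):
            raise ValueError(f"unknown log_base {self.log_base!r}")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        chain = ChainConfig(**raw.pop("chain", {}))
        trees = {
            taxon: ([p] if isinstance(p, str) else list(p))
            for taxon, p in (raw.pop("trees", {}) or {}).items()
        }
        return cls(chain=chain, trees=trees, **raw)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["treeless_taxa"] = list(self.treeless_taxa)
        return d


@dataclass
class ResultsBundle:
    """All outputs of one run, plus reproducibility metadata."""

    metrics: pd.DataFrame
    summary: pd.DataFrame
    taxon_table: pd.DataFrame
    pooled_table: pd.DataFrame
    pooled_fit_mcmc: RegressionFit | None
    pooled_fit_gls: RegressionFit | None
    pooled_samples: pd.DataFrame | None
    pooled_data: pd.DataFrame | None
    taxon_fits: dict[str, list[RegressionFit]]
    taxon_samples: dict[str, pd.DataFrame]
    skipped: dict[str, str]
    manifest: dict[str, list[str]]
    metadata: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.tsv", sep="\t", index=False,
                            float_format="%.10g")
        self.summary.to_csv(out / "taxon_summary.tsv", sep="\t",
                            float_format="%.10g")
        self.taxon_table.to_csv(out / "taxon_fits.tsv", sep="\t", index=False,
                                float_format="%.10g")
        self.pooled_table.to_csv(out / "pooled_fit.tsv", sep="\t", index=False,
                                 float_format="%.10g")
        if self.pooled_samples is not None:
            self.pooled_samples.to_csv(out / "pooled_samples.tsv", sep="\t",
                                       index=False, float_format="%.10g")
        meta = dict(self.metadata)
        meta["skipped"] = self.skipped
        meta["manifest"] = self.manifest
        (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def _transform_response(p: np.ndarray, transform: str, log_base: str) -> np.ndarray:
    if transform == "identity":
        return p
    if transform == "log":
        out = np.log(p)
    elif transform == "logit":
        # proportions of exactly 1 are pulled just inside the boundary
        q = np.clip(p, 1e-12, 1.0 - 1e-9)
        out = np.log(q / (1.0 - q))
    if log_base == "base10":
        out = out / np.log(10.0)
    return out


def _predictor(n: np.ndarray, log_base: str) -> np.ndarray:
    x = np.log(n)
    return x / np.log(10.0) if log_base == "base10" else x


def run_analysis(cfg: AnalysisConfig, dataset: Dataset | None = None) -> ResultsBundle:
    """Run the full comparative analysis.

    ``dataset`` can be passed directly (e.g. a synthetic one); otherwise
    the trait table is read from ``cfg.trait_table``.
    """
    ds = dataset if dataset is not None else read_species_table(cfg.trait_table)
    logger.info("loaded %d species from %s", len(ds), ds.provenance)
    metrics = compute_metrics(ds)
    summary = taxon_summary(ds)

    rng = np.random.default_rng(cfg.seed)
    taxa = list(dict.fromkeys(metrics["taxon_group"]))
    multi = metrics[metrics["social_category"] == MULTI_BREEDER]

    taxon_rows = []
    taxon_fits: dict[str, list[RegressionFit]] = {}
    taxon_samples: dict[str, pd.DataFrame] = {}
    skipped: dict[str, str] = {}
    manifest: dict[str, list[str]] = {}

    for taxon in taxa:
        sub = multi[multi["taxon_group"] == taxon]
        if len(sub) < cfg.min_multibreeder:
            skipped[taxon] = (
                f"only {len(sub)} multi-breeder species (< {cfg.min_multibreeder})"
            )
            logger.info("skipping %s: %s", taxon, skipped[taxon])
            continue
        tree_paths = cfg.trees.get(taxon, [])
        if not tree_paths and taxon not in cfg.treeless_taxa:
            skipped[taxon] = "no tree supplied and not flagged tree-less"
            logger.info("skipping %s: %s", taxon, skipped[taxon])
            continue

        fits: list[RegressionFit] = []
        taxon_seed = int(rng.integers(2**31))
        for k, tree_path in enumerate(tree_paths or [None]):
            if tree_path is None:
                corr = None
                species = list(sub["species_id"])
            else:
                tree = read_newick(tree_path)
                present = set(tip_labels(tree))
                species = [s for s in sub["species_id"] if s in present]
                dropped = [s for s in sub["species_id"] if s not in present]
                if dropped:
                    manifest.setdefault(taxon, []).extend(dropped)
                    logger.info(
                        "%s: %d species absent from tree %s", taxon, len(dropped),
                        tree_path,
                    )
                if len(species) < cfg.min_multibreeder:
                    continue
                pruned = prune_to_taxa(tree, species)
                corr = correlation_from_tree(pruned).reorder(species)
            rows = sub.set_index("species_id").loc[species]
            y = _transform_response(
                rows["proportion_breeders"].to_numpy(), cfg.transform, cfg.log_base
            )
            x = _predictor(rows["N"].to_numpy(), cfg.log_base)
            chain = cfg.chain.replace(seed=taxon_seed + k)
            fit, samples = mixed_mcmc(y, x, corr=corr, config=chain)
            fit.n_obs = len(species)
            fits.append(fit)
            taxon_samples[taxon] = samples
        if not fits:
            skipped[taxon] = "no tree retained enough multi-breeder species"
            continue
        taxon_fits[taxon] = fits
        # average parameter estimates across candidate trees
        slope_stats = np.mean(
            [f.coefficients.loc["slope", ["mean", "lower_95", "upper_95", "p"]]
             .to_numpy(dtype=float) for f in fits],
            axis=0,
        )
        int_stats = np.mean(
            [f.coefficients.loc["intercept", ["mean", "lower_95", "upper_95", "p"]]
             .to_numpy(dtype=float) for f in fits],
            axis=0,
        )
        taxon_rows.append(
            {
                "taxon": taxon,
                "n": int(np.mean([f.n_obs for f in fits])),
                "n_trees": len(fits),
                "posterior_mean": slope_stats[0],
                "lower_95": slope_stats[1],
                "upper_95": slope_stats[2],
                "p_mcmc": slope_stats[3],
                "intercept_mean": int_stats[0],
                "intercept_lower_95": int_stats[1],
                "intercept_upper_95": int_stats[2],
            }
        )
        logger.info(
            "%s: n=%d slope=%.3f [%.3f, %.3f]", taxon, taxon_rows[-1]["n"],
            slope_stats[0], slope_stats[1], slope_stats[2],
        )

    taxon_table = pd.DataFrame(
        taxon_rows,
        columns=[
            "taxon", "n", "n_trees", "posterior_mean", "lower_95", "upper_95",
            "p_mcmc", "intercept_mean", "intercept_lower_95", "intercept_upper_95",
        ],
    )

    # pooled model: taxonomic class as a random intercept
    pooled_fit_mcmc = pooled_fit_gls = None
    pooled_samples = pooled_data = None
    pooled_rows = []
    if len(multi) >= cfg.min_multibreeder and multi["taxon_group"].nunique() >= 1:
        y = _transform_response(
            multi["proportion_breeders"].to_numpy(), cfg.transform, cfg.log_base
        )
        x = _predictor(multi["N"].to_numpy(), cfg.log_base)
        pooled_seed = int(rng.integers(2**31))
        groups = multi["taxon_group"].to_numpy()
        use_groups = multi["taxon_group"].nunique() >= 2
        pooled_fit_mcmc, pooled_samples = mixed_mcmc(
            y, x, groups=groups if use_groups else None,
            config=cfg.chain.replace(seed=pooled_seed),
        )
        pooled_fit_mcmc.n_obs = len(multi)
        gls = PhylogeneticGLS().fit(x, y, corr=None)
        pooled_fit_gls = gls.fit_
        pooled_data = pd.DataFrame(
            {"species_id": multi["species_id"], "taxon_group": groups, "x": x, "y": y}
        )
        for fit in (pooled_fit_mcmc, pooled_fit_gls):
            row = fit.coefficients.loc["slope"]
            pooled_rows.append(
                {
                    "model": fit.method,
                    "n": len(multi),
                    "posterior_mean": row["mean"],
                    "lower_95": row["lower_95"],
                    "upper_95": row["upper_95"],
                    "p": row["p"],
                    "intercept": fit.intercept,
                }
            )
        logger.info(
            "pooled: n=%d slope=%.3f [%.3f, %.3f]", len(multi),
            pooled_rows[0]["posterior_mean"], pooled_rows[0]["lower_95"],
            pooled_rows[0]["upper_95"],
        )
    else:
        logger.info(
            "no pooled regression: only %d multi-breeder species", len(multi)
        )

    pooled_table = pd.DataFrame(
        pooled_rows,
        columns=["model", "n", "posterior_mean", "lower_95", "upper_95", "p",
                 "intercept"],
    )

    bundle = ResultsBundle(
        metrics=metrics,
        summary=summary,
        taxon_table=taxon_table,
        pooled_table=pooled_table,
        pooled_fit_mcmc=pooled_fit_mcmc,
        pooled_fit_gls=pooled_fit_gls,
        pooled_samples=pooled_samples,
        pooled_data=pooled_data,
        taxon_fits=taxon_fits,
        taxon_samples=taxon_samples,
        skipped=skipped,
        manifest=manifest,
        metadata={
            "seed": cfg.seed,
            "config": cfg.to_dict(),
            "phylosoc_version": __version__,
            "n_species": len(ds),
        },
    )
    if cfg.out_dir:
        bundle.write(cfg.out_dir)
    return bundle


def export_figure_tables(bundle: ResultsBundle, out_dir: str | Path,
                         n_grid: int = 50, n_bins: int = 12) -> dict[str, Path]:
    """Write plot-ready TSVs for the three standard displays.

    * breeder proportion vs. group size, pooled (scatter + regression
      line with pointwise 95% band on a log grid + sampling histograms);
    * the same per taxon;
    * monopolization index vs. group size (scatter + histograms).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    metrics = bundle.metrics
    insect = metrics["taxon_group"].isin(["wasp", "ant"])

    # --- pooled proportion-vs-size figure -------------------------------
    rows = []
    multi = metrics[metrics["social_category"] == MULTI_BREEDER]
    for _, r in multi.iterrows():
        rows.append(
            {"kind": "point", "series": r["taxon_group"], "x": np.log(r["N"]),
             "y": r["proportion_breeders"]}
        )
    if bundle.pooled_data is not None:
        x = bundle.pooled_data["x"].to_numpy()
        grid = np.linspace(x.min(), x.max(), n_grid)
        if bundle.pooled_fit_gls is not None:
            f = bundle.pooled_fit_gls
            est_cov = getattr(f, "cov_params_", None)
            for fitname, fit in (("pgls", bundle.pooled_fit_gls),
                                 ("mcmc", bundle.pooled_fit_mcmc)):
                if fit is None:
                    continue
                if fitname == "mcmc" and bundle.pooled_samples is not None:
                    a = bundle.pooled_samples["intercept"].to_numpy()
                    b = bundle.pooled_samples["slope"].to_numpy()
                    lines = a[None, :] + np.outer(grid, b)
                    mid = lines.mean(axis=1)
                    lo = np.percentile(lines, 2.5, axis=1)
                    hi = np.percentile(lines, 97.5, axis=1)
                else:
                    mid = fit.intercept + fit.slope * grid
                    lo = hi = None
                for i, g in enumerate(grid):
                    rows.append(
                        {"kind": f"line_{fitname}", "series": "pooled", "x": g,
                         "y": mid[i],
                         "lower": lo[i] if lo is not None else np.nan,
                         "upper": hi[i] if hi is not None else np.nan}
                    )
    for series, mask in (("insect", insect), ("vertebrate", ~insect)):
        vals = np.log(metrics.loc[mask, "N"].to_numpy())
        if len(vals):
            counts, edges = np.histogram(vals, bins=n_bins)
            for c, e0, e1 in zip(counts, edges[:-1], edges[1:]):
                rows.append({"kind": "hist", "series": series, "x": (e0 + e1) / 2,
                             "y": int(c), "lower": e0, "upper": e1})
    fig1 = pd.DataFrame(rows)
    written["proportion_vs_size_pooled"] = out / "fig_proportion_vs_size_pooled.tsv"
    fig1.to_csv(written["proportion_vs_size_pooled"], sep="\t", index=False,
                float_format="%.10g")

    # --- per-taxon figure ----------------------------------------------
    rows = []
    for taxon, fits in bundle.taxon_fits.items():
        sub = multi[multi["taxon_group"] == taxon]
        for _, r in sub.iterrows():
            rows.append({"kind": "point", "series": taxon, "x": np.log(r["N"]),
                         "y": r["proportion_breeders"]})
        xs = np.log(sub["N"].to_numpy())
        grid = np.linspace(xs.min(), xs.max(), n_grid)
        samples = bundle.taxon_samples.get(taxon)
        mean_int = np.mean([f.intercept for f in fits])
        mean_slope = np.mean([f.slope for f in fits])
        for i, g in enumerate(grid):
            row = {"kind": "line_mcmc", "series": taxon, "x": g,
                   "y": mean_int + mean_slope * g, "lower": np.nan, "upper": np.nan}
            if samples is not None:
                draws = samples["intercept"].to_numpy() + g * samples["slope"].to_numpy()
                row["lower"] = np.percentile(draws, 2.5)
                row["upper"] = np.percentile(draws, 97.5)
            rows.append(row)
    fig2 = pd.DataFrame(rows)
    written["proportion_vs_size_by_taxon"] = out / "fig_proportion_vs_size_by_taxon.tsv"
    fig2.to_csv(written["proportion_vs_size_by_taxon"], sep="\t", index=False,
                float_format="%.10g")

    # --- monopolization figure -----------------------------------------
    rows = []
    defined = metrics[metrics["N"] > 1]
    for _, r in defined.iterrows():
        rows.append({"kind": "point", "series": r["taxon_group"],
                     "x": np.log(r["N"]), "y": r["monopolization"]})
    for series, mask in (("insect", insect), ("vertebrate", ~insect)):
        vals = np.log(metrics.loc[mask & (metrics["N"] > 1), "N"].to_numpy())
        if len(vals):
            counts, edges = np.histogram(vals, bins=n_bins)
            for c, e0, e1 in zip(counts, edges[:-1], edges[1:]):
                rows.append({"kind": "hist", "series": series, "x": (e0 + e1) / 2,
                             "y": int(c), "lower": e0, "upper": e1})
    fig3 = pd.DataFrame(rows)
    written["monopolization_vs_size"] = out / "fig_monopolization_vs_size.tsv"
    fig3.to_csv(written["monopolization_vs_size"], sep="\t", index=False,
                float_format="%.10g")
    return written
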