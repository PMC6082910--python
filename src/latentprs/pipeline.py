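"""Configuration, file I/O and end-to-end pipeline orchestration.

``run_pipeline`` executes the full analysis on files referenced from a
YAML configuration: PRS construction per trait and P-value threshold,
the respondent inclusion filter, the four measurement structures with a
fit-statistics table, omega reliability from the bifactor solution, and
the structural PRS associations with permutation-adjusted and
IPW-weighted sensitivity variants.  Every JSON artifact embeds a
provenance stamp (config hash, seed set, package version), and all
randomness flows from the named seeds in the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    estimate_factor_scores,
    estimate_ipw,
    fit_structural,
    permutation_adjusted_p,
    weighted_structural,
)
from .measurement import (
    STRUCTURES,
    MeasurementModel,
    apply_inclusion_filter,
)
from .prs import (
    GenotypeMatrix,
    PolygenicScorer,
    prs_correlation_report,
    read_summary_stats,
)
from .reliability import compute_omegas

__all__ = ["PipelineConfig", "run_pipeline", "read_items", "read_block_map"]

log = logging.getLogger("latentprs")


@dataclass
class PipelineConfig:
    """Paths, thresholds, seeds and options for one pipeline run."""

    items: str
    blocks: str
    genotypes: str
    sumstats: dict  # trait name -> file path
    covariates: str | None = None
    p_thresholds: tuple = (0.5, 0.05, 1e-5, 5e-8)
    primary_threshold: float = 0.05
    structures: tuple = ("correlated", "bifactor")
    min_per_block: int = 4
    n_perm: int = 1000
    n_integration_points: int = 8000
    category_base: int = 0  # input dialect: categories coded from 0 or 1
    seed: int = 0
    out_dir: str = "latentprs_output"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        paths = [self.items, self.blocks, self.genotypes, *self.sumstats.values()]
        if self.covariates:
            paths.append(self.covariates)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"configured paths do not exist: {missing}")
        for s in self.structures:
            if s not in STRUCTURES:
                raise ValueError(f"unknown structure {s!r}")

    def content_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_block_map(path) -> dict:
    with open(path) as fh:
        blocks = yaml.safe_load(fh)
    if not isinstance(blocks, dict):
        raise ValueError("block map must be a mapping of item -> block")
    return blocks


def read_items(path, block_map: dict, category_base: int = 0) -> pd.DataFrame:
    """Item CSV (respondent id column first) validated against a block map.

    Category labels are remapped deterministically to 0..K-1 per item
    (sorted observed values); unknown items in the block map raise, and
    non-integer or negative codes become missing with a warning.
    """
    df = pd.read_csv(path, index_col=0)
    unknown = [c for c in df.columns if c not in block_map]
    if unknown:
        raise ValueError(f"items not present in block map: {unknown[:5]}")
    out = {}
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce") - category_base
        bad = vals.notna() & ((vals < 0) | (vals != vals.round()))
        if bad.any():
            warnings.warn(f"{int(bad.sum())} out-of-range values in item {col!r} set missing")
            vals[bad] = np.nan
        observed = np.sort(vals.dropna().unique())
        remap = {v: i for i, v in enumerate(observed)}
        out[col] = vals.map(remap)
    return pd.DataFrame(out, index=df.index)


def _read_genotypes(path) -> GenotypeMatrix:
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return GenotypeMatrix.from_vcf(path)
    return GenotypeMatrix.from_dosage_tsv(path)


def _stamp(cfg: PipelineConfig) -> dict:
    return {
        "package": "latentprs",
        "version": __version__,
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
    }


def _write_json(path: Path, payload: dict) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serialisable: {type(o)}")

    path.write_text(json.dumps(payload, indent=2, default=default))


def run_pipeline(config: PipelineConfig, out_dir: str | None = None) -> dict:
    """Execute PRS -> filter -> measurement -> reliability -> association.

    Returns the report bundle as a dict; artifacts are also written under
    ``out_dir``.  A failure in any stage aborts with the stage name while
    earlier artifacts remain on disk.
    """
    config.validate()
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(config)
    bundle: dict = {"provenance": stamp}
    stage = "setup"
    try:
        stage = "prs"
        log.info("stage %s", stage)
        geno = _read_genotypes(config.genotypes)
        scores_primary = {}
        prs_provenance = {}
        for trait, path in config.sumstats.items():
            stats = read_summary_stats(path)
            per_thresh = {}
            skipped = {}
            for pt in config.p_thresholds:
                try:
                    scorer = PolygenicScorer(sumstats=stats, p_threshold=pt).fit(geno)
                except ValueError as err:
                    skipped[f"pt_{pt:g}"] = str(err)
                    continue
                sc = scorer.score_set(geno)
                per_thresh[pt] = sc
                if pt == config.primary_threshold:
                    scores_primary[trait] = sc
            if config.primary_threshold not in per_thresh:
                raise ValueError(
                    f"trait {trait!r}: no SNPs at the primary threshold "
                    f"{config.primary_threshold:g}"
                )
            pd.DataFrame(
                {f"pt_{pt:g}": s.to_series() for pt, s in per_thresh.items()}
            ).to_csv(out / f"prs_{trait}.csv")
            prs_provenance[trait] = {
                f"pt_{pt:g}": {
                    "n_snps": s.n_snps_used,
                    "dropped": [list(d) for d in s.dropped],
                }
                for pt, s in per_thresh.items()
            }
            prs_provenance[trait].update(
                {k: {"n_snps": 0, "skipped": v} for k, v in skipped.items()}
            )
        _write_json(out / "prs_provenance.json", {**stamp, "traits": prs_provenance})
        if len(scores_primary) >= 2:
            corr = prs_correlation_report(
                {t: s for t, s in scores_primary.items()}
            )
            corr.to_csv(out / "prs_correlations.csv")
            bundle["prs_correlations"] = corr.to_dict()

        stage = "filter"
        log.info("stage %s", stage)
        blocks = read_block_map(config.blocks)
        items = read_items(config.items, blocks, category_base=config.category_base)
        items_f, filter_report = apply_inclusion_filter(
            items, blocks, min_per_block=config.min_per_block
        )
        genotyped = items_f.index.isin(geno.samples)
        analysis_items = items_f.loc[genotyped]
        filter_report["n_with_genotypes"] = int(genotyped.sum())
        bundle["filter"] = filter_report

        stage = "measurement"
        log.info("stage %s", stage)
        fits = {}
        rows = []
        for structure in STRUCTURES:
            mm = MeasurementModel(
                structure=structure,
                item_blocks=blocks,
                information_criteria=True,
                n_integration_points=config.n_integration_points,
                random_state=config.seed,
            ).fit(analysis_items)
            fits[structure] = mm
            fi = mm.fit_indices_
            rows.append(
                {
                    "model": structure,
                    "n_parameters": mm.result_.n_parameters,
                    "aic": fi.aic,
                    "bic": fi.bic,
                    "ssa_bic": fi.ssa_bic,
                    "rmsea": fi.rmsea,
                    "rmsea_90ci": f"({fi.rmsea_ci[0]:.3f}, {fi.rmsea_ci[1]:.3f})",
                    "cfi": fi.cfi,
                    "tli": fi.tli,
                }
            )
        fit_table = pd.DataFrame(rows)
        fit_table.to_csv(out / "fit_table.csv", index=False)
        bundle["fit_table"] = fit_table.to_dict(orient="records")
        _write_json(
            out / "measurement_bifactor.json",
            {
                **stamp,
                "loadings": fits["bifactor"].loadings_.to_dict(),
                "thresholds": [t.tolist() for t in fits["bifactor"].thresholds_],
                "rmsea_convention": "n in the denominator",
            },
        )

        stage = "reliability"
        log.info("stage %s", stage)
        omegas = compute_omegas(fits["bifactor"].result_)
        _write_json(out / "omega.json", {**stamp, **omegas.to_dict()})
        bundle["omega"] = omegas.to_dict()

        stage = "association"
        log.info("stage %s", stage)
        assoc_rows = []
        perm_rows = []
        rng = np.random.default_rng(config.seed)
        ipw = None
        if config.covariates:
            cov = pd.read_csv(config.covariates, index_col=0)
            cov = cov.reindex(items.index)
            included = items.index.isin(analysis_items.index)
            ipw = estimate_ipw(included.astype(float), cov)
            ipw_weights = pd.Series(ipw.weight, index=items.index)
        for trait, score in scores_primary.items():
            prs_series = score.to_series().reindex(analysis_items.index)
            mask = prs_series.notna()
            items_t = analysis_items.loc[mask]
            prs_t = prs_series.loc[mask]
            for structure in config.structures:
                res = fit_structural(items_t, prs_t, structure, item_blocks=blocks)
                wres = None
                if ipw is not None:
                    w = ipw_weights.reindex(items_t.index).to_numpy()
                    wres = weighted_structural(
                        items_t, prs_t, structure, ipw=w, item_blocks=blocks
                    )
                for _, row in res.table.iterrows():
                    rec = {
                        "trait": trait,
                        "structure": structure,
                        "outcome": row["outcome"],
                        "beta": row["beta"],
                        "lci": row["lci"],
                        "uci": row["uci"],
                        "p": row["p"],
                        "n": res.n_analyzed,
                    }
                    if wres is not None:
                        wrow = wres.table.set_index("outcome").loc[row["outcome"]]
                        rec.update(
                            beta_ipw=wrow["beta"], lci_ipw=wrow["lci"],
                            uci_ipw=wrow["uci"], p_ipw=wrow["p"],
                        )
                    assoc_rows.append(rec)
                if structure == "bifactor":
                    fscores = estimate_factor_scores(res.measurement, items_t)
                    perm = permutation_adjusted_p(
                        fscores,
                        prs_t.to_numpy(),
                        n_perm=config.n_perm,
                        seed=int(rng.integers(2**31)),
                    )
                    for _, row in perm.table.iterrows():
                        perm_rows.append({"trait": trait, **row.to_dict()})
        assoc = pd.DataFrame(assoc_rows)
        assoc.to_csv(out / "associations.csv", index=False)
        bundle["associations"] = assoc.to_dict(orient="records")
        if perm_rows:
            perm_df = pd.DataFrame(perm_rows)
            perm_df.to_csv(out / "permutation_adjusted.csv", index=False)
            bundle["permutation"] = perm_df.to_dict(orient="records")

        _write_json(out / "bundle.json", bundle)
    except Exception as err:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err
    return bundle
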