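"""End-to-end orchestration of the headline analyses.

Two entry points compose the stage modules: :func:`run_bias_analysis`
(architecture table, length-bias curves, Monte Carlo repeat-density
enrichment of target gene sets) and :func:`run_signature_analysis`
(binarization, widely-expressed/uninformative filtering, one-vs-one SVM
tissue signature).  Every run writes a JSON manifest echoing all
parameters, the seed and package versions, which suffices to reproduce
any output byte-identically.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classifier import (
    BinaryTissueClassifier,
    binarize,
    filter_uninformative,
    flag_widely_expressed,
)
from .enrichment import MCConfig, MonteCarloEnrichment
from .expression import read_expression, read_labels
from .genes import architecture_table, read_gene_models, read_gene_set
from .length_bias import cumulative_delta
from .repeats import density_table, read_repeatmasker

log = logging.getLogger("archrep")

MEASURES = ("exonic_length", "intronic_length", "exonic_content")


@dataclass
class PipelineConfig:
    """Inputs, stage parameters (defaults are the published thresholds) and seed."""

    gtf: str = ""
    rmsk: str = ""
    rmsk_dialect: str = "rmsk_tsv"
    gene_sets: dict[str, str] = field(default_factory=dict)  # name -> path
    background: str = ""  # path; empty = all annotated genes
    expression: str = ""
    labels: str = ""
    outdir: str = "archrep_out"
    seed: int = 0
    mc_iterations: int = 10_000
    z_threshold: float = 2.0
    fdr_threshold: float = 0.05
    rank_de_fdr: float = 0.01
    binarize_min_abundance: float = 2.0
    binarize_top_fraction: float = 0.5
    widely_expressed_fraction: float = 0.9
    uninformative_fraction: float = 0.5
    svm_C: float = 1.0
    cv_folds: int = 10
    other_threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _write_manifest(config: PipelineConfig, outdir: Path, stage: str, extra: dict) -> None:
    import numpy, pandas, scipy, sklearn

    manifest = {
        "stage": stage,
        "archrep_version": __version__,
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "scikit-learn": sklearn.__version__,
        },
        "parameters": asdict(config),
        **extra,
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2))


def run_bias_analysis(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Architecture, length-bias curves, and MC enrichment of each gene set."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.gtf or not config.rmsk or not config.gene_sets:
        raise ValueError("bias analysis needs gtf, rmsk and at least one gene set")

    log.info("stage=read_annotation gtf=%s", config.gtf)
    genes = read_gene_models(config.gtf)
    annotation = read_repeatmasker(config.rmsk, dialect=config.rmsk_dialect)
    arch = architecture_table(genes.values())
    arch.to_csv(outdir / "architecture.tsv", sep="\t")

    background = (
        read_gene_set(config.background) if config.background else sorted(genes)
    )
    log.info("stage=density genes=%d families=%d", len(genes), len(annotation.families))
    densities = density_table(genes, annotation)
    densities.to_csv(outdir / "density.tsv", sep="\t", index=False)

    outputs: dict[str, pd.DataFrame] = {"architecture": arch, "density": densities}
    mc_cfg = MCConfig(
        iterations=config.mc_iterations,
        seed=config.seed,
        z_threshold=config.z_threshold,
        fdr_threshold=config.fdr_threshold,
    )
    for name, path in config.gene_sets.items():
        target = read_gene_set(path)
        if not target:
            raise ValueError(f"gene set {name!r} is empty")
        log.info("stage=enrichment set=%s n=%d", name, len(target))
        results = MonteCarloEnrichment(densities, target, background, mc_cfg).fit()
        results.to_tsv(str(outdir / f"enrichment_{name}.tsv"))
        results.heatmap_matrix().to_csv(outdir / f"heatmap_{name}.tsv", sep="\t")
        outputs[f"enrichment_{name}"] = results.table

        bg_arch = arch.loc[arch.index.intersection(background)]
        set_arch = arch.loc[arch.index.intersection(target)]
        curve_rows = []
        for measure in MEASURES:
            curve = cumulative_delta(set_arch[measure], bg_arch[measure])
            df = curve.to_frame()
            df.insert(0, "measure", measure)
            curve_rows.append(df)
        curves = pd.concat(curve_rows, ignore_index=True)
        curves.to_csv(outdir / f"lengthbias_{name}.tsv", sep="\t", index=False)
        outputs[f"lengthbias_{name}"] = curves

    _write_manifest(config, outdir, "bias", {"wall_time_s": round(time.time() - t0, 2)})
    return outputs


def run_signature_analysis(config: PipelineConfig) -> dict:
    """Binarize, filter, train the one-vs-one SVM, report confusion and VI."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not config.expression or not config.labels:
        raise ValueError("signature analysis needs expression and labels")

    matrix = read_expression(config.expression)
    labels = read_labels(config.labels)
    log.info("stage=binarize genes=%d samples=%d", *matrix.shape)
    binary = binarize(
        matrix,
        min_abundance=config.binarize_min_abundance,
        top_fraction=config.binarize_top_fraction,
    )
    widely = flag_widely_expressed(binary, labels, config.widely_expressed_fraction)
    retained = filter_uninformative(binary, labels, config.uninformative_fraction)
    features = sorted((retained - widely))
    log.info(
        "stage=filter widely=%d retained=%d features=%d",
        len(widely), len(retained), len(features),
    )
    binary_used = binary.loc[features]
    binary_used.astype(int).to_csv(outdir / "binary_matrix.tsv", sep="\t")
    pd.Series(sorted(widely), name="gene_id").to_csv(
        outdir / "widely_expressed.tsv", sep="\t", index=False
    )

    model = BinaryTissueClassifier(
        binary_used,
        labels,
        C=config.svm_C,
        folds=config.cv_folds,
        other_threshold=config.other_threshold,
    )
    results = model.fit(seed=config.seed)
    results.signature.to_csv(outdir / "variable_importance.tsv", sep="\t")
    results.confusion_percent.to_csv(outdir / "confusion.tsv", sep="\t")
    results.predictions.to_csv(outdir / "predictions.tsv", sep="\t")
    _write_manifest(
        config, outdir, "signature",
        {"wall_time_s": round(time.time() - t0, 2), "cv_accuracy": results.accuracy},
    )
    return {
        "binary": binary_used,
        "widely_expressed": widely,
        "results": results,
    }


def setup_logging(verbose: bool = False, logfile: str | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
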