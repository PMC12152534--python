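"""End-to-end orchestration: model load/adapt -> phase constraint ->
sampling -> high-producer selection -> skew test -> overlap, enrichment,
PCA and transport signature, with a run manifest for reproducibility.

Identical config + seed gives byte-identical CSV artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import MetabolicModel
from .omics import ExpressionTable, build_phase_model
from .sampler import FluxSampleSet, sample_model, validate_samples
from .sbml import read_sbml, write_sbml
from .signatures import (
    extract_transport_signature,
    infer_transport_annotation,
    overlap_counts,
    pca_solutions,
    select_high_producers,
    significant_reactions,
    skew_results_frame,
    subsystem_enrichment,
    test_flux_skew,
)
from .synthetic import (
    SyntheticExpressionConfig,
    ToyModelConfig,
    generate_synthetic_expression,
    generate_toy_model,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@contextmanager
def _stage(name: str):
    logger.info("stage: %s", name)
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(name, exc) from exc


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from YAML via :meth:`from_yaml`."""

    output_dir: str = "fluxsig_run"
    # inputs: either paths or synthetic configs
    model_path: str | None = None
    toy_model: ToyModelConfig | None = None
    expression_path: str | None = None
    phase_path: str | None = None
    synthetic_expression: SyntheticExpressionConfig | None = None
    # analysis settings
    product_reaction_id: str | None = None
    total_iterations: int = 50_000
    thinning: int = 10
    seed: int = 0
    warmup: int | None = None
    rounding: bool = True
    percentile: float = 95.0
    fdr_threshold: float = 0.05
    top_k: int = 50
    pool: str = "full"
    or_mode: str = "max"
    scaling: float | None = None
    make_plots: bool = False

    def validate(self) -> None:
        if self.model_path is None and self.toy_model is None:
            raise ValueError("config needs model_path or a toy_model block")
        if (
            self.expression_path is None or self.phase_path is None
        ) and self.synthetic_expression is None:
            raise ValueError(
                "config needs expression_path+phase_path or a synthetic_expression block"
            )
        if not (0 < self.percentile < 100):
            raise ValueError("percentile must be in (0, 100)")
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.thinning < 1 or self.total_iterations < self.thinning:
            raise ValueError("need total_iterations >= thinning >= 1")
        for p in (self.model_path, self.expression_path, self.phase_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "toy_model" in raw and raw["toy_model"] is not None:
            raw["toy_model"] = ToyModelConfig(**raw["toy_model"])
        if "synthetic_expression" in raw and raw["synthetic_expression"] is not None:
            block = dict(raw["synthetic_expression"])
            if "phases" in block:
                block["phases"] = tuple((str(a), int(b)) for a, b in block["phases"])
            if "planted_fold_changes" in block:
                block["planted_fold_changes"] = {
                    (str(g), str(p)): float(fc)
                    for (g, p), fc in (
                        ((e["gene"], e["phase"]), e["fold_change"])
                        for e in block["planted_fold_changes"]
                    )
                }
            raw["synthetic_expression"] = SyntheticExpressionConfig(**block)
        return cls(**raw)

    def to_jsonable(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            return obj

        return conv(dataclasses.asdict(self))


def _phase_seed(seed: int, index: int) -> int:
    return int(
        np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31)
    )


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the whole workflow; returns the output directory.

    Artifacts: per-phase bound audits, flux samples (compressed CSV +
    metadata sidecar), skew-test tables, enrichment tables, PCA summaries
    and transport signatures; cross-phase overlap counts; a manifest
    recording the config hash, derived seeds and package versions.
    """
    with _stage("config"):
        config.validate()
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)

    with _stage("load_model"):
        if config.model_path is not None:
            model: MetabolicModel = read_sbml(config.model_path)
        else:
            model, truth = generate_toy_model(config.toy_model)
            write_sbml(model, out / "toy_model.xml")
            (out / "toy_ground_truth.json").write_text(
                json.dumps(
                    {
                        "coupled_reactions": truth.coupled_reactions,
                        "uncoupled_reactions": truth.uncoupled_reactions,
                        "product_reaction_id": truth.product_reaction_id,
                        "heavy_seq": truth.heavy_seq,
                        "light_seq": truth.light_seq,
                    },
                    indent=2,
                )
            )
        product_id = config.product_reaction_id or model.product_reaction_id
        if not product_id:
            raise ValueError("no product reaction id in config or model")

    with _stage("load_expression"):
        if config.expression_path is not None:
            table = ExpressionTable.from_csv(config.expression_path, config.phase_path)
        else:
            table = generate_synthetic_expression(model, config.synthetic_expression)
            table.to_csv(out / "expression.csv", out / "phases.csv")
        phases = table.phases

    per_phase_sets: dict[str, set[str]] = {}
    signature_tables: list[pd.DataFrame] = []
    pca_rows: list[tuple[str, int, float]] = []
    phase_seeds: dict[str, int] = {}
    annotation = infer_transport_annotation(model)

    for i, phase in enumerate(phases):
        with _stage(f"constrain[{phase}]"):
            pm = build_phase_model(
                model, table, phase,
                scaling=config.scaling, or_mode=config.or_mode,
            )
            _write_csv(pm.bounds_audit, out / f"bounds_{phase}.csv")

        with _stage(f"sample[{phase}]"):
            seed = _phase_seed(config.seed, i)
            phase_seeds[phase] = seed
            samples: FluxSampleSet = sample_model(
                pm.model,
                total_iterations=config.total_iterations,
                thinning=config.thinning,
                seed=seed,
                warmup=config.warmup,
                rounding=config.rounding,
                phase=phase,
            )
            ok, report = validate_samples(samples, pm.model)
            if not ok:
                raise RuntimeError(f"stored samples violate constraints: {report}")
            samples.save(out / f"samples_{phase}")

        with _stage(f"select[{phase}]"):
            selection = select_high_producers(samples, product_id, config.percentile)

        with _stage(f"skew_test[{phase}]"):
            results = test_flux_skew(
                samples, selection,
                fdr_threshold=config.fdr_threshold, pool=config.pool,
            )
            _write_csv(skew_results_frame(results), out / f"skew_{phase}.csv")
            per_phase_sets[phase] = significant_reactions(results, config.fdr_threshold)

        with _stage(f"enrichment[{phase}]"):
            enrich = subsystem_enrichment(results, model, config.fdr_threshold)
            _write_csv(enrich, out / f"enrichment_{phase}.csv")

        with _stage(f"pca[{phase}]"):
            high = samples.to_frame().iloc[selection.indices]
            pca = pca_solutions(high)
            for c, pct in enumerate(pca.explained_variance_pct, start=1):
                pca_rows.append((phase, c, float(pct)))
            loadings = pca.loadings.reset_index(names="reaction")
            _write_csv(loadings, out / f"pca_loadings_{phase}.csv")

        with _stage(f"signature[{phase}]"):
            sig = extract_transport_signature(
                pca.loadings, results, samples, selection, annotation,
                top_k=config.top_k, fdr_threshold=config.fdr_threshold,
                phase=phase,
            )
            signature_tables.append(sig)

        if config.make_plots:
            with _stage(f"plots[{phase}]"):
                from . import plots

                plots.pca_scatter(
                    pca, out / f"fig_pca_{phase}.png", title=f"high producers, {phase}"
                )
                plots.enrichment_dotplot(enrich, out / f"fig_enrichment_{phase}.png")
                if len(sig):
                    plots.signature_bars(sig, out / f"fig_signature_{phase}.png")

    with _stage("overlap"):
        if len(phases) >= 2:
            counts = overlap_counts(per_phase_sets)
            frame = pd.DataFrame(
                [("+".join(k), v) for k, v in sorted(counts.items())],
                columns=["phases", "n_reactions"],
            )
            _write_csv(frame, out / "overlap_counts.csv")

    with _stage("signature"):
        signature = (
            pd.concat(signature_tables, ignore_index=True)
            if signature_tables
            else pd.DataFrame()
        )
        _write_csv(signature, out / "signature.csv")
        _write_csv(
            pd.DataFrame(pca_rows, columns=["phase", "component", "explained_variance_pct"]),
            out / "pca_variance.csv",
        )

    with _stage("manifest"):
        cfg = config.to_jsonable()
        cfg_hash = hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()
        manifest = {
            "config": cfg,
            "config_sha256": cfg_hash,
            "phase_seeds": phase_seeds,
            "product_reaction_id": product_id,
            "versions": {
                "fluxsig": __version__,
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return out
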