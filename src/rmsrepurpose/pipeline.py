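"""End-to-end orchestration: generate/load -> preprocess -> train both
models -> predict external lines -> consensus report.

A run is driven by a :class:`RunConfig`, either in synthetic mode
(a panel is generated with planted signal) or in file mode (panel and
response TSVs on disk). One global seed fans out deterministically to
per-stage seeds, every stage's outputs are written as TSV, and a JSON
manifest records configuration, seeds, timings and file hashes so runs
are self-describing and repeatable bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aenn import AENNClassifier, SingleClassDrugError, panel_layers, predict_external
from .consensus import select_candidates
from .panel import OmicsPanel, read_response_table, write_response_table, write_truth
from .preprocess import align_panels, preprocess_panel
from .superfelt import SuperFeltClassifier, predict_majority
from .synthetic import PanelConfig, generate_panel, make_external_lines

logger = logging.getLogger(__name__)

AENN_LAYERS = ("expression", "cn_binary")
SUPERFELT_LAYERS = ("expression", "cn_binary", "mutation")


def stage_seed(stage: str, global_seed: int) -> int:
    """Deterministic per-stage seed derived from the stage name."""
    ss = np.random.SeedSequence([global_seed, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % 2**31)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``panel_config`` (synthetic mode) or
    ``panel_dir``/``responses_path`` (file mode) must be provided.
    """

    out_dir: str | Path = "run_output"
    seed: int = 0
    panel_config: PanelConfig | None = None
    panel_dir: str | Path | None = None
    responses_path: str | Path | None = None
    external_dir: str | Path | None = None
    n_external: int = 2
    keep_fraction: float = 0.2
    aenn_params: dict = field(default_factory=dict)
    superfelt_params: dict = field(default_factory=dict)
    k: int = 5
    require_consistency: str = "both"

    def __post_init__(self) -> None:
        synthetic = self.panel_config is not None
        file_mode = self.panel_dir is not None or self.responses_path is not None
        if synthetic == file_mode:
            raise ValueError(
                "provide either panel_config (synthetic mode) or "
                "panel_dir + responses_path (file mode), not both"
            )


#: compact defaults for the model stages of a pipeline run
DEFAULT_AENN = dict(
    bottleneck_dim=16, ae_hidden_dims=(64,), classifier_hidden_dims=(32,),
    ae_epochs=15, learning_rate=0.01, batch_size=16,
)
DEFAULT_SUPERFELT = dict(
    embedding_dim=16, encoder_hidden_dims=(32,), classifier_hidden_dims=(16,),
    encoder_epochs=8, classifier_epochs=8, learning_rate=0.01, batch_size=32,
)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _drug_y(responses: pd.DataFrame, drug: str, cell_ids: list[str]) -> np.ndarray:
    return responses.loc[drug].reindex(cell_ids).to_numpy(dtype=float)


def train_models(panel, responses, layer_names, estimator_factory):
    """Fit one estimator per drug; single-class drugs get SKIPPED status.

    Returns (models dict, metrics DataFrame indexed by drug).
    """
    models, rows = {}, []
    layers = panel_layers(panel, layer_names)
    for drug in responses.index:
        y = _drug_y(responses, drug, panel.cell_ids)
        est = estimator_factory(drug)
        try:
            est.fit(layers, y)
        except SingleClassDrugError as err:
            logger.warning("drug %s SKIPPED: %s", drug, err)
            rows.append({"drug": drug, "auc": np.nan, "f1": np.nan,
                         "threshold": np.nan, "status": "SKIPPED"})
            continue
        models[drug] = est
        rows.append(
            {
                "drug": drug,
                "auc": est.cv_auc_,
                "f1": est.cv_f1_,
                "threshold": getattr(est, "threshold_", np.nan),
                "status": "OK",
            }
        )
    return models, pd.DataFrame(rows).set_index("drug")


def _records_frame(records) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "config": {
            "keep_fraction": config.keep_fraction,
            "k": config.k,
            "require_consistency": config.require_consistency,
            "aenn_params": {**DEFAULT_AENN, **config.aenn_params},
            "superfelt_params": {**DEFAULT_SUPERFELT, **config.superfelt_params},
        },
    }

    def record_stage(name: str, started: float, outputs: list[Path]) -> None:
        manifest["stages"].append(
            {
                "name": name,
                "seconds": round(time.perf_counter() - started, 3),
                "outputs": {p.name: _sha256(p) for p in outputs},
            }
        )

    # ------------------------------------------------------- stage: inputs
    t0 = time.perf_counter()
    if config.panel_config is not None:
        cfg = dataclasses.replace(
            config.panel_config, seed=stage_seed("generate", config.seed)
        )
        manifest["config"]["panel_config"] = dataclasses.asdict(cfg)
        panel, responses, truth = generate_panel(cfg)
        external, external_labels = make_external_lines(
            panel, truth, config.n_external,
            cfg.platform_shift_sd, stage_seed("external", config.seed),
        )
        panel.to_dir(out / "panel")
        write_response_table(responses, out / "responses.tsv")
        external.to_dir(out / "external_panel")
        write_response_table(external_labels, out / "external_truth_labels.tsv")
        write_truth(truth.to_jsonable(), out / "truth.json")
        stage_outputs = [out / "responses.tsv", out / "truth.json",
                         out / "external_truth_labels.tsv"]
    else:
        for path in (config.panel_dir, config.responses_path):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"missing input: {path}")
        panel = OmicsPanel.from_dir(config.panel_dir)
        responses = read_response_table(config.responses_path)
        if config.external_dir is None:
            raise ValueError("file mode requires external_dir")
        if not Path(config.external_dir).exists():
            raise FileNotFoundError(f"missing input: {config.external_dir}")
        external = OmicsPanel.from_dir(config.external_dir)
        external_labels = None
        stage_outputs = []
    record_stage("inputs", t0, stage_outputs)

    # --------------------------------------------------- stage: preprocess
    t0 = time.perf_counter()
    train_pre = preprocess_panel(panel, keep_fraction=config.keep_fraction)
    # one gene universe for all layers: the variance-retained genes
    genes = list(train_pre.expression.columns)
    train_pre.cn_min = train_pre.cn_min[genes]
    train_pre.cn_max = train_pre.cn_max[genes]
    train_pre.cn_binary = train_pre.cn_binary[genes]
    train_pre.mutation = train_pre.mutation[genes]
    ext_pre = preprocess_panel(external, keep_fraction=None)
    train_pre, ext_pre = align_panels(train_pre, ext_pre)
    train_pre.to_dir(out / "panel_preprocessed")
    ext_pre.to_dir(out / "external_preprocessed")
    record_stage("preprocess", t0, [])

    # --------------------------------------------------- stage: train aenn
    t0 = time.perf_counter()
    aenn_seed = stage_seed("aenn", config.seed)
    aenn_params = {**DEFAULT_AENN, **config.aenn_params}
    aenn_models, aenn_metrics = train_models(
        train_pre, responses, AENN_LAYERS,
        lambda drug: AENNClassifier(
            seed=(aenn_seed + zlib.crc32(drug.encode())) % 2**31, **aenn_params
        ),
    )
    aenn_metrics.to_csv(out / "aenn_cv_metrics.tsv", sep="\t")
    record_stage("train_aenn", t0, [out / "aenn_cv_metrics.tsv"])

    # ---------------------------------------------- stage: train superfelt
    t0 = time.perf_counter()
    sf_seed = stage_seed("superfelt", config.seed)
    sf_params = {**DEFAULT_SUPERFELT, **config.superfelt_params}
    sf_models, sf_metrics = train_models(
        train_pre, responses, SUPERFELT_LAYERS,
        lambda drug: SuperFeltClassifier(
            seed=(sf_seed + zlib.crc32(drug.encode())) % 2**31, **sf_params
        ),
    )
    sf_metrics.to_csv(out / "superfelt_cv_metrics.tsv", sep="\t")
    record_stage("train_superfelt", t0, [out / "superfelt_cv_metrics.tsv"])

    # ------------------------------------------------- stage: predictions
    t0 = time.perf_counter()
    ext_cells = ext_pre.cell_ids
    aenn_records, sf_records = [], []
    for drug, model in aenn_models.items():
        aenn_records += predict_external(
            model, panel_layers(ext_pre, AENN_LAYERS), ext_cells, drug
        )
    for drug, model in sf_models.items():
        sf_records += predict_majority(
            model, panel_layers(ext_pre, SUPERFELT_LAYERS), ext_cells, drug
        )
    aenn_pred = _records_frame(aenn_records)
    sf_pred = _records_frame(sf_records)
    aenn_pred.to_csv(out / "aenn_predictions.tsv", sep="\t", index=False)
    sf_pred.to_csv(out / "superfelt_predictions.tsv", sep="\t", index=False)
    record_stage(
        "predict", t0, [out / "aenn_predictions.tsv", out / "superfelt_predictions.tsv"]
    )

    # --------------------------------------------------- stage: consensus
    t0 = time.perf_counter()
    report_paths = []
    for cell in ext_cells:
        a = aenn_pred[aenn_pred["cell_id"] == cell].set_index("drug_id")["call"]
        s = sf_pred[sf_pred["cell_id"] == cell].set_index("drug_id")["call"]
        report = select_candidates(
            a, s, aenn_metrics[aenn_metrics["status"] == "OK"],
            k=config.k, require_consistency=config.require_consistency, cell_id=cell,
        )
        path = out / f"candidates_{cell}.tsv"
        report.write_tsv(path)
        report_paths.append(path)
    record_stage("consensus", t0, report_paths)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    summary = [
        f"rmsrepurpose v{__version__} run (seed={config.seed})",
        f"cell lines: {panel.n_cell_lines}, drugs: {len(responses)}, "
        f"genes after preprocessing: {train_pre.expression.shape[1]}",
        f"AE-NN mean CV AUC: {aenn_metrics['auc'].mean():.3f}",
        f"Super.FELT mean CV AUC: {sf_metrics['auc'].mean():.3f}",
        f"external lines scored: {len(ext_cells)}",
    ]
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    return manifest
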