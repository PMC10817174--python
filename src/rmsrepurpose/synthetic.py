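"""Synthetic pharmacogenomic panel generator with planted drug-response signal.

Emulates the training data the pipeline expects from a large cell-line
screen: log-scale expression with gene-specific means and variances,
integer gene-level copy numbers around the cell-line ploidy (with
occasional in-gene breakpoints so min and max copies differ), somatic
variant records carrying a consequence class, and per-drug binary
response labels generated from a logistic model over a small set of
informative genes. Copy-number gains feed back into expression (gene
dosage), so the expression and copy-number layers are correlated.

External test lines are drawn from the same generative model and then
distorted by per-gene multiplicative/additive perturbations, mimicking
the platform gap between a public screen and in-house profiling of the
same biology.

The planted truth (informative genes, weights, per-line response
probabilities) is returned alongside the data so that recovery of the
signal by the downstream models can be tested quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .panel import OmicsPanel

CONSEQUENCES = ("silent", "missense", "nonsense", "frameshift")
_CONSEQUENCE_P = (0.30, 0.45, 0.15, 0.10)

#: additive log2-expression shift per log2 copy-ratio unit (gene dosage)
DOSAGE_COUPLING = 0.5

#: fraction of copy-number events whose min and max copies differ
BREAKPOINT_FRACTION = 0.1

#: number of co-expression modules and the within-module correlation of
#: gene z-scores; transcriptomes are strongly modular, which is what
#: makes unsupervised compression of expression informative at all
N_MODULES = 10
MODULE_CORRELATION = 0.6

#: informative genes are drawn from this top fraction of genes by
#: dispersion — response biomarkers are differentially active genes,
#: which is also what lets a variance filter retain them
INFORMATIVE_POOL_FRACTION = 0.4


@dataclass(frozen=True)
class PanelConfig:
    """Study-design parameters of a synthetic panel.

    Defaults describe the regime the pipeline targets: hundreds of
    training lines, a strongly informative minority-class signal on a
    small gene subset, and moderate mutation / copy-number event rates.
    """

    n_cell_lines: int = 400
    n_genes: int = 200
    n_drugs: int = 5
    n_informative_genes: int = 10
    effect_size: float = 2.0
    sensitive_prevalence: float = 0.15
    cn_event_rate: float = 0.08
    mutation_rate: float = 0.02
    platform_shift_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)) or isinstance(self.seed, bool):
            raise TypeError("seed must be an integer")
        for name in ("n_cell_lines", "n_genes", "n_drugs", "n_informative_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.n_informative_genes > self.n_genes:
            raise ValueError("n_informative_genes cannot exceed n_genes")
        for name in ("sensitive_prevalence", "cn_event_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie strictly inside (0, 1)")
        if self.effect_size < 0 or self.platform_shift_sd < 0:
            raise ValueError("effect_size and platform_shift_sd must be >= 0")


@dataclass
class SyntheticTruth:
    """Planted ground truth plus the generator state needed to extend it."""

    informative_gene_ids: dict[str, list[str]]
    true_weights: dict[str, np.ndarray]
    true_response_prob: pd.DataFrame  # drug x cell line
    intercepts: dict[str, float] = field(default_factory=dict)
    gene_means: pd.Series | None = None
    gene_sds: pd.Series | None = None
    gene_modules: np.ndarray | None = None
    config: PanelConfig | None = None

    def to_jsonable(self) -> dict:
        return {
            "informative_gene_ids": self.informative_gene_ids,
            "true_weights": {d: list(map(float, w)) for d, w in self.true_weights.items()},
            "intercepts": {d: float(c) for d, c in self.intercepts.items()},
            "true_response_prob": {
                d: dict(zip(self.true_response_prob.columns,
                            map(float, self.true_response_prob.loc[d])))
                for d in self.true_response_prob.index
            },
        }


def _draw_copy_numbers(rng, ploidy, n_genes, event_rate):
    """Integer min/max copies per gene around each line's ploidy."""
    n = len(ploidy)
    baseline = np.rint(ploidy).astype(int)[:, None] * np.ones((1, n_genes), int)
    cn = baseline.copy()
    events = rng.random((n, n_genes)) < event_rate
    amp = rng.random((n, n_genes)) < 0.5
    gain = rng.integers(1, 5, size=(n, n_genes))
    loss = rng.integers(1, 3, size=(n, n_genes))
    cn = np.where(events & amp, baseline + gain, cn)
    cn = np.where(events & ~amp, np.maximum(baseline - loss, 0), cn)
    cn_min, cn_max = cn.copy(), cn.copy()
    brk = events & (rng.random((n, n_genes)) < BREAKPOINT_FRACTION)
    cn_max = np.where(brk & amp, cn_max + 1, cn_max)
    cn_min = np.where(brk & ~amp, np.maximum(cn_min - 1, 0), cn_min)
    return cn_min, cn_max


def _dosage_shift(cn_min, cn_max, ploidy):
    """log2 copy ratio of the more extreme call, times the coupling factor."""
    lo = np.log2(np.maximum(cn_min, 0.25) / ploidy[:, None])
    hi = np.log2(np.maximum(cn_max, 0.25) / ploidy[:, None])
    ratio = np.where(np.abs(hi) >= np.abs(lo), hi, lo)
    return DOSAGE_COUPLING * ratio


def _draw_variants(rng, cell_ids, gene_ids, mutation_rate):
    hits = np.argwhere(rng.random((len(cell_ids), len(gene_ids))) < mutation_rate)
    cons = rng.choice(CONSEQUENCES, size=len(hits), p=_CONSEQUENCE_P)
    return pd.DataFrame(
        {
            "cell_line": [cell_ids[i] for i, _ in hits],
            "gene": [gene_ids[j] for _, j in hits],
            "consequence": cons,
        }
    )


def _draw_expression(rng, n_lines, gene_means, gene_sds, gene_modules):
    """Modular expression: per-line module factors shared within modules."""
    factors = rng.standard_normal((n_lines, N_MODULES))
    eps = rng.standard_normal((n_lines, len(gene_means)))
    z = (
        np.sqrt(MODULE_CORRELATION) * factors[:, gene_modules]
        + np.sqrt(1.0 - MODULE_CORRELATION) * eps
    )
    return gene_means + gene_sds * z


def _pick_informative(rng, gene_modules, gene_sds, n_informative) -> np.ndarray:
    """Markers for one drug: variable genes from one co-expression module.

    Drug response tracks the activity of a pathway whose member genes
    co-vary, so the planted markers share a module; within the module
    the most dispersed genes are preferred (biomarkers are
    differentially active, which also lets a variance filter keep
    them). Neighbouring modules supplement small ones.
    """
    n_modules = int(gene_modules.max()) + 1
    m = int(rng.integers(0, n_modules))
    candidates: list[int] = []
    for step in range(n_modules):
        members = np.flatnonzero(gene_modules == (m + step) % n_modules)
        members = members[np.argsort(-gene_sds[members], kind="stable")]
        pool = max(n_informative, int(INFORMATIVE_POOL_FRACTION * len(members)))
        candidates.extend(members[:pool])
        if len(candidates) >= n_informative:
            break
    return rng.choice(np.array(candidates[: 2 * n_informative]),
                      size=n_informative, replace=False)


def _solve_intercept(scores: np.ndarray, prevalence: float) -> float:
    """Intercept c with mean(sigmoid(scores + c)) == prevalence."""

    def gap(c):
        return expit(scores + c).mean() - prevalence

    return brentq(gap, -60.0, 60.0, xtol=1e-10)


def generate_panel(
    config: PanelConfig,
) -> tuple[OmicsPanel, pd.DataFrame, SyntheticTruth]:
    """Generate a panel, its drug-response table and the planted truth.

    Returns
    -------
    panel : OmicsPanel
    responses : DataFrame
        Drug x cell-line table of 0/1 labels (no NA in synthetic data).
    truth : SyntheticTruth
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cell_ids = [f"CL{i:04d}" for i in range(cfg.n_cell_lines)]
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    drug_ids = [f"DRUG{i:03d}" for i in range(cfg.n_drugs)]

    gene_means = rng.uniform(3.0, 10.0, cfg.n_genes)
    gene_sds = rng.uniform(0.4, 1.2, cfg.n_genes)
    gene_modules = rng.integers(0, N_MODULES, cfg.n_genes)
    ploidy = rng.choice([2.0, 3.0, 4.0], size=cfg.n_cell_lines, p=[0.8, 0.15, 0.05])

    cn_min, cn_max = _draw_copy_numbers(rng, ploidy, cfg.n_genes, cfg.cn_event_rate)
    expr = _draw_expression(rng, cfg.n_cell_lines, gene_means, gene_sds, gene_modules)
    expr = expr + _dosage_shift(cn_min, cn_max, ploidy) * gene_sds
    variants = _draw_variants(rng, cell_ids, gene_ids, cfg.mutation_rate)

    informative: dict[str, list[str]] = {}
    weights: dict[str, np.ndarray] = {}
    intercepts: dict[str, float] = {}
    probs = np.empty((cfg.n_drugs, cfg.n_cell_lines))
    labels = np.empty((cfg.n_drugs, cfg.n_cell_lines))
    for d, drug in enumerate(drug_ids):
        idx = _pick_informative(rng, gene_modules, gene_sds, cfg.n_informative_genes)
        # pathway-like signal: one driving module, coherent direction
        w = cfg.effect_size * rng.choice([-1.0, 1.0]) * rng.uniform(
            0.5, 1.5, cfg.n_informative_genes
        )
        z = (expr[:, idx] - gene_means[idx]) / gene_sds[idx]
        score = z @ w
        c = _solve_intercept(score, cfg.sensitive_prevalence)
        p = expit(score + c)
        labels[d] = rng.random(cfg.n_cell_lines) < p
        probs[d] = p
        informative[drug] = [gene_ids[i] for i in idx]
        weights[drug] = w
        intercepts[drug] = c

    panel = OmicsPanel(
        expression=pd.DataFrame(expr, index=cell_ids, columns=gene_ids),
        cn_min=pd.DataFrame(cn_min, index=cell_ids, columns=gene_ids),
        cn_max=pd.DataFrame(cn_max, index=cell_ids, columns=gene_ids),
        ploidy=pd.Series(ploidy, index=cell_ids, name="ploidy"),
        variants=variants,
    )
    responses = pd.DataFrame(labels, index=pd.Index(drug_ids, name="drug"),
                             columns=cell_ids)
    truth = SyntheticTruth(
        informative_gene_ids=informative,
        true_weights=weights,
        true_response_prob=pd.DataFrame(probs, index=drug_ids, columns=cell_ids),
        intercepts=intercepts,
        gene_means=pd.Series(gene_means, index=gene_ids),
        gene_sds=pd.Series(gene_sds, index=gene_ids),
        gene_modules=gene_modules,
        config=cfg,
    )
    return panel, responses, truth


def oracle_score(truth: SyntheticTruth, expression: pd.DataFrame, drug: str) -> np.ndarray:
    """Linear score w . z of the planted model — the Bayes-optimal ranking."""
    genes = truth.informative_gene_ids[drug]
    z = (expression[genes] - truth.gene_means[genes]) / truth.gene_sds[genes]
    return z.to_numpy() @ truth.true_weights[drug]


def make_external_lines(
    panel: OmicsPanel,
    truth: SyntheticTruth,
    n_external: int,
    shift_sd: float,
    seed: int,
) -> tuple[OmicsPanel, pd.DataFrame]:
    """Draw platform-shifted external test lines from the same model.

    New cell lines come from the generative model recorded in ``truth``;
    their expression is then distorted per gene by ``x -> a*x + b`` with
    ``a ~ 1 + N(0, shift_sd)`` and ``b ~ N(0, shift_sd)``, and copy
    numbers are re-drawn independently. The planted response label of
    each external line for every drug is returned alongside the panel.
    """
    if n_external < 1:
        raise ValueError("n_external must be >= 1")
    if shift_sd < 0:
        raise ValueError("shift_sd must be >= 0")
    cfg = truth.config
    if cfg is None or truth.gene_means is None:
        raise ValueError("truth does not carry the generator state")

    rng = np.random.default_rng(seed)
    gene_ids = list(truth.gene_means.index)
    cell_ids = [f"EXT{i:04d}" for i in range(n_external)]
    means = truth.gene_means.to_numpy()
    sds = truth.gene_sds.to_numpy()

    ploidy = rng.choice([2.0, 3.0, 4.0], size=n_external, p=[0.8, 0.15, 0.05])
    cn_min, cn_max = _draw_copy_numbers(rng, ploidy, len(gene_ids), cfg.cn_event_rate)
    expr = _draw_expression(rng, n_external, means, sds, truth.gene_modules)
    expr = expr + _dosage_shift(cn_min, cn_max, ploidy) * sds
    variants = _draw_variants(rng, cell_ids, gene_ids, cfg.mutation_rate)

    drug_ids = list(truth.true_response_prob.index)
    labels = np.empty((len(drug_ids), n_external))
    for d, drug in enumerate(drug_ids):
        genes = truth.informative_gene_ids[drug]
        idx = [gene_ids.index(g) for g in genes]
        z = (expr[:, idx] - means[idx]) / sds[idx]
        p = expit(z @ truth.true_weights[drug] + truth.intercepts[drug])
        labels[d] = rng.random(n_external) < p

    # platform distortion drawn last so shift_sd=0 reproduces the same lines
    scale = 1.0 + shift_sd * rng.standard_normal(len(gene_ids))
    offset = shift_sd * rng.standard_normal(len(gene_ids))
    shifted = expr * scale + offset

    external = OmicsPanel(
        expression=pd.DataFrame(shifted, index=cell_ids, columns=gene_ids),
        cn_min=pd.DataFrame(cn_min, index=cell_ids, columns=gene_ids),
        cn_max=pd.DataFrame(cn_max, index=cell_ids, columns=gene_ids),
        ploidy=pd.Series(ploidy, index=cell_ids, name="ploidy"),
        variants=variants,
    )
    responses = pd.DataFrame(labels, index=pd.Index(drug_ids, name="drug"),
                             columns=cell_ids)
    return external, responses
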