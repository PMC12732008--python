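"""DAG-informed conditional adversarial twin generator.

A digital twin cohort is a synthetic, patient-level replica of a source
cohort.  Here it is produced by a conditional generative adversarial model
tailored to small clinical tables:

* Generation is conditioned on key clinical covariates (by default USVT
  site, treatment arm, age, sex and active cancer).  For 1:1 twin cohorts
  the conditioning values are taken from the training rows themselves, so
  the conditioned margins match the source exactly.
* A directed acyclic graph (DAG) of assumed clinical dependencies
  constrains the wiring: variables are generated in topological order and
  each DAG node's generator head sees only its parents (conditioned or
  previously generated) as context.  Outcomes are terminal nodes — they are
  generated jointly with the covariates but can never be conditioned on.
* Categorical and binary outputs use concrete (Gumbel-softmax /
  binary-concrete) relaxations during adversarial training and hard
  sampling at generation time; continuous outputs are z-scored with
  domain-closure clipping at generation.

The generator and discriminator are small dense networks trained with
alternating single-step Adam updates on a binary cross-entropy objective.
Convergence is declared when the moving averages of both losses stabilize;
fidelity metrics (:mod:`usvtwin.fidelity`) remain the post-hoc arbiter of
twin quality.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from usvtwin.cohort import Cohort, VariableSpec, default_schema
from usvtwin.nn import MLP, bce_grad, bce_with_logits, sigmoid, softmax

__all__ = [
    "DAGSpec",
    "GANConfig",
    "GeneratorModel",
    "default_dag",
    "train_cgan",
    "generate_twins",
    "replicate_twins",
    "check_convergence",
]

DEFAULT_CONDITIONING = ("usvt_site", "treatment", "age", "sex", "active_cancer")
DEFAULT_OUTCOMES = ("recanalization", "recurrence", "major_bleed")


@dataclass(frozen=True)
class DAGSpec:
    """Clinical dependency graph constraining generation order and wiring."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    terminal_outcomes: tuple[str, ...]

    def __post_init__(self) -> None:
        g = self.graph()
        if set(e for pair in self.edges for e in pair) - set(self.nodes):
            raise ValueError("edge endpoints must be declared nodes")
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("dependency graph must be acyclic")
        for node in self.terminal_outcomes:
            if g.out_degree(node) > 0:
                raise ValueError(f"terminal outcome {node!r} has outgoing edges")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    def parents(self, node: str) -> tuple[str, ...]:
        return tuple(p for p, c in self.edges if c == node)

    def ancestors(self, node: str) -> set[str]:
        return nx.ancestors(self.graph(), node)

    @classmethod
    def from_yaml(cls, path) -> "DAGSpec":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            tuple(data["nodes"]),
            tuple((p, c) for p, c in data["edges"]),
            tuple(data["terminal_outcomes"]),
        )


def default_dag() -> DAGSpec:
    """Expert-style default: every key covariate feeds every outcome."""
    covariates = DEFAULT_CONDITIONING
    edges = tuple((p, c) for c in DEFAULT_OUTCOMES for p in covariates)
    return DAGSpec(covariates + DEFAULT_OUTCOMES, edges, DEFAULT_OUTCOMES)


@dataclass
class GANConfig:
    latent_dim: int = 16
    generator_widths: tuple[int, ...] = (64, 64)
    discriminator_widths: tuple[int, ...] = (64, 64)
    epochs: int = 2000
    batch_size: int = 32
    learning_rates: tuple[float, float] = (1e-3, 1e-3)  # (generator, discriminator)
    conditioning_vars: tuple[str, ...] = DEFAULT_CONDITIONING
    convergence_window: int = 100
    convergence_tol: float = 0.05
    temperature: float = 0.66
    #: sd of Gaussian instance noise added to every discriminator input —
    #: the key regularizer against discriminator memorization at n≈90
    instance_noise: float = 0.4
    domain_slack: float = 0.05
    early_stop: bool = False
    seed: int = 0


@dataclass
class _GenVar:
    """One generated variable: its head, encoding and conditioning context."""

    name: str
    kind: str  # continuous | binary | categorical
    levels: tuple[str, ...]
    context: tuple[str, ...]
    out_dim: int
    head: MLP | None = None
    slice: slice | None = None


class _Blocks:
    """Column layout of an encoded variable group."""

    def __init__(self) -> None:
        self.slices: dict[str, slice] = {}
        self.width = 0

    def add(self, name: str, width: int) -> slice:
        sl = slice(self.width, self.width + width)
        self.slices[name] = sl
        self.width += width
        return sl


def _var_width(spec: VariableSpec) -> int:
    return len(spec.levels) if spec.kind == "categorical" else 1


@dataclass
class GeneratorModel:
    """A trained conditional generator with its preprocessing maps."""

    gen_vars: list[_GenVar]
    cond_blocks: _Blocks
    gen_blocks: _Blocks
    cont_stats: dict[str, tuple[float, float]]  # name -> (mean, std)
    cont_bounds: dict[str, tuple[float, float]]  # name -> training (min, max)
    schema: list[VariableSpec]
    dag: DAGSpec
    config: GANConfig
    loss_history: dict[str, list[float]]
    converged: bool
    train_conditioning: pd.DataFrame  # raw conditioning columns of training rows
    n_train: int
    version: int = 1

    @property
    def context_map(self) -> dict[str, tuple[str, ...]]:
        """Which variables each generator head may see — the structural
        surface for DAG-compliance checks."""
        return {gv.name: gv.context for gv in self.gen_vars}

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @classmethod
    def load(cls, path) -> "GeneratorModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, cls):
            raise TypeError("not a GeneratorModel checkpoint")
        return model


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def _encode_column(df: pd.DataFrame, spec: VariableSpec, stats: dict) -> np.ndarray:
    col = df[spec.name]
    if spec.kind == "categorical":
        out = np.zeros((len(df), len(spec.levels)))
        for j, lvl in enumerate(spec.levels):
            out[:, j] = (col == lvl).astype(float)
        return out
    if spec.kind == "binary":
        return col.fillna(0).to_numpy(dtype=float)[:, None]
    mean, std = stats[spec.name]
    z = (col.to_numpy(dtype=float) - mean) / std
    return np.nan_to_num(z, nan=0.0)[:, None]


def _internal_specs(schema: Sequence[VariableSpec]) -> list[VariableSpec]:
    """Schema rewritten for generation: follow-up imaging availability is
    modeled explicitly and recanalization becomes a binary complete-flag."""
    out: list[VariableSpec] = []
    for s in schema:
        if s.name == "recanalization":
            out.append(VariableSpec("recan_observed", "binary"))
            out.append(VariableSpec("recanalization", "binary"))
        else:
            out.append(s)
    return out


def _internal_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["recan_observed"] = df["recanalization"].notna().astype(int)
    out["recanalization"] = (df["recanalization"] == "complete").astype(int)
    return out


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train_cgan(
    cohort: Cohort,
    dag: DAGSpec | None = None,
    config: GANConfig | None = None,
) -> GeneratorModel:
    """Train the conditional adversarial generator on *cohort*.

    Deterministic for a fixed ``config.seed``.  Returns a model whose
    ``converged`` flag reports whether the generator/discriminator losses
    stabilized (moving-average criterion); non-convergence is flagged, not
    raised, since twin acceptability is judged post hoc by fidelity metrics.
    """
    dag = dag or default_dag()
    config = config or GANConfig()
    if len(cohort) == 0:
        raise ValueError("cannot train on an empty cohort")
    schema_names = {s.name for s in cohort.schema}
    if not set(dag.nodes) <= schema_names:
        raise ValueError("DAG nodes must be schema variables")
    if set(config.conditioning_vars) & set(dag.terminal_outcomes):
        raise ValueError("conditioning variables may not include terminal outcomes")
    if not set(config.conditioning_vars) <= schema_names:
        raise ValueError("conditioning variables must be schema variables")

    rng = np.random.default_rng(config.seed)
    specs = _internal_specs(cohort.schema)
    spec_by_name = {s.name: s for s in specs}
    data = _internal_frame(cohort.df)

    cont_stats: dict[str, tuple[float, float]] = {}
    cont_bounds: dict[str, tuple[float, float]] = {}
    for s in specs:
        if s.kind == "continuous":
            vals = data[s.name].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                mean, std, lo, hi = 0.0, 1.0, 0.0, 0.0
            else:
                mean = float(vals.mean())
                std = float(vals.std())
                lo, hi = float(vals.min()), float(vals.max())
            cont_stats[s.name] = (mean, std if std > 0 else 1.0)
            cont_bounds[s.name] = (lo, hi)

    # generation order: DAG nodes topologically, then the remaining variables
    topo = list(nx.topological_sort(dag.graph()))
    gen_names = [n for n in topo if n not in config.conditioning_vars]
    gen_names += [
        s.name
        for s in specs
        if s.name not in config.conditioning_vars and s.name not in dag.nodes
    ]

    cond_blocks = _Blocks()
    for name in config.conditioning_vars:
        cond_blocks.add(name, _var_width(spec_by_name[name]))
    gen_blocks = _Blocks()
    gen_vars: list[_GenVar] = []
    dag_nodes = set(dag.nodes)
    for name in gen_names:
        s = spec_by_name[name]
        context = dag.parents(name) if name in dag_nodes else tuple(config.conditioning_vars)
        width = _var_width(s)
        sl = gen_blocks.add(name, width)
        gv = _GenVar(name, s.kind, s.levels, context, width, slice=sl)
        ctx_dim = sum(
            cond_blocks.slices[c].stop - cond_blocks.slices[c].start
            if c in cond_blocks.slices
            else gen_blocks.slices[c].stop - gen_blocks.slices[c].start
            for c in context
        )
        gv.head = MLP(config.latent_dim + ctx_dim, config.generator_widths, width, rng)
        gen_vars.append(gv)

    disc = MLP(cond_blocks.width + gen_blocks.width, config.discriminator_widths, 1, rng)

    cond_enc = np.hstack(
        [_encode_column(data, spec_by_name[n], cont_stats) for n in config.conditioning_vars]
    )
    gen_enc = np.hstack(
        [_encode_column(data, spec_by_name[gv.name], cont_stats) for gv in gen_vars]
    )

    n = len(data)
    lr_g, lr_d = config.learning_rates
    tau = config.temperature
    loss_history: dict[str, list[float]] = {"generator": [], "discriminator": []}

    def gen_forward(cond_b: np.ndarray, batch_rng: np.random.Generator):
        """Soft (relaxed) generation; returns the fake block and per-head caches."""
        bsz = cond_b.shape[0]
        z = batch_rng.normal(size=(bsz, config.latent_dim))
        fake = np.zeros((bsz, gen_blocks.width))
        caches = []
        for gv in gen_vars:
            parts = [z]
            for c in gv.context:
                if c in cond_blocks.slices:
                    parts.append(cond_b[:, cond_blocks.slices[c]])
                else:
                    parts.append(fake[:, gen_blocks.slices[c]])
            raw = gv.head.forward(np.hstack(parts))
            if gv.kind == "continuous":
                y = raw
                cache = None
            elif gv.kind == "binary":
                # straight-through binary concrete: the discriminator sees a
                # hard 0/1 sample (so it cannot key on relaxation softness),
                # gradients flow through the soft sigmoid
                g = batch_rng.logistic(size=raw.shape)
                cache = sigmoid((raw + g) / tau)
                y = (raw + g > 0).astype(float)
            else:
                g = batch_rng.gumbel(size=raw.shape)
                cache = softmax((raw + g) / tau)
                y = np.zeros_like(raw)
                y[np.arange(len(raw)), np.argmax(raw + g, axis=1)] = 1.0
            fake[:, gv.slice] = y
            caches.append(cache)
        return fake, caches

    def gen_backward(dfake: np.ndarray, caches) -> None:
        # gradients into generated parents used as context by later heads are
        # dropped (stop-gradient); each head learns from the discriminator's
        # direct view of its own output
        for gv, cache in zip(reversed(gen_vars), reversed(caches)):
            dy = dfake[:, gv.slice]
            if gv.kind == "continuous":
                draw = dy
            elif gv.kind == "binary":
                draw = dy * cache * (1.0 - cache) / tau
            else:
                inner = (dy * cache).sum(axis=1, keepdims=True)
                draw = cache * (dy - inner) / tau
            gv.head.backward(draw)

    n_batches = max(1, int(np.ceil(n / config.batch_size)))
    stopped = False
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        d_losses, g_losses = [], []
        for b in range(n_batches):
            idx = order[b * config.batch_size : (b + 1) * config.batch_size]
            if len(idx) == 0:
                continue
            cond_b = cond_enc[idx]
            real_b = gen_enc[idx]
            fake_b, caches = gen_forward(cond_b, rng)
            noise = lambda shape: config.instance_noise * rng.normal(size=shape)
            real_in = np.hstack([cond_b, real_b])
            fake_in = np.hstack([cond_b, fake_b])
            real_in += noise(real_in.shape)
            fake_noisy = fake_in + noise(fake_in.shape)

            # discriminator step (one-sided label smoothing on real)
            logits_r = disc.forward(real_in)
            loss_r = bce_with_logits(logits_r, np.ones_like(logits_r))
            disc.backward(bce_grad(logits_r, 0.9 * np.ones_like(logits_r)))
            logits_f = disc.forward(fake_noisy)
            loss_f = bce_with_logits(logits_f, np.zeros_like(logits_f))
            disc.backward(bce_grad(logits_f, np.zeros_like(logits_f)))
            disc.step(lr_d)
            d_losses.append(0.5 * (loss_r + loss_f))

            # generator step (non-saturating loss)
            logits_g = disc.forward(fake_in + noise(fake_in.shape))
            g_losses.append(bce_with_logits(logits_g, np.ones_like(logits_g)))
            dx = disc.backward(bce_grad(logits_g, np.ones_like(logits_g)))
            disc.zero_grads()
            gen_backward(dx[:, cond_blocks.width :], caches)
            for gv in gen_vars:
                gv.head.step(lr_g)

        loss_history["discriminator"].append(float(np.mean(d_losses)))
        loss_history["generator"].append(float(np.mean(g_losses)))
        if (
            config.early_stop
            and epoch + 1 >= max(2 * config.convergence_window, 500)
            and check_convergence(loss_history, config.convergence_window, config.convergence_tol)
        ):
            stopped = True
            break

    converged = check_convergence(
        loss_history,
        min(config.convergence_window, len(loss_history["generator"])),
        config.convergence_tol,
    )

    return GeneratorModel(
        gen_vars=gen_vars,
        cond_blocks=cond_blocks,
        gen_blocks=gen_blocks,
        cont_stats=cont_stats,
        cont_bounds=cont_bounds,
        schema=list(cohort.schema),
        dag=dag,
        config=config,
        loss_history=loss_history,
        converged=converged or stopped,
        train_conditioning=cohort.df.loc[:, list(config.conditioning_vars)].copy(),
        n_train=n,
    )


def check_convergence(
    loss_history: Mapping[str, Sequence[float]] | Sequence[float],
    window: int,
    tol: float,
) -> bool:
    """True iff the moving average of every loss series has stabilized.

    Over the last ``window`` epochs, the means of the first and second half
    must differ by at most ``tol`` relative to the first half's magnitude.
    """
    if window < 2:
        raise ValueError("window must be at least 2")
    series = (
        list(loss_history.values())
        if isinstance(loss_history, Mapping)
        else [loss_history]
    )
    for values in series:
        values = np.asarray(values, dtype=float)
        if len(values) < window:
            raise ValueError("loss history shorter than the convergence window")
        tail = values[-window:]
        half = window // 2
        first, second = tail[:half].mean(), tail[half:].mean()
        denom = max(abs(first), 1e-12)
        if abs(second - first) / denom > tol:
            return False
    return True


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def generate_twins(
    model: GeneratorModel,
    n: int,
    conditions: Mapping[str, object] | None = None,
    seed: int | None = None,
) -> Cohort:
    """Sample *n* digital-twin records from a trained model.

    Conditioning rows are reused from the training cohort (resampled with
    replacement when ``n`` differs from the training size), which guarantees
    the conditioned margins match the source.  Entries of *conditions*
    override the corresponding conditioning variable for every record;
    conditioning on a terminal outcome is a contract error.
    """
    conditions = dict(conditions or {})
    for key in conditions:
        if key in model.dag.terminal_outcomes:
            raise ValueError(f"cannot condition on terminal outcome {key!r}")
        if key not in model.config.conditioning_vars:
            raise ValueError(f"{key!r} is not a conditioning variable")
    rng = np.random.default_rng(model.config.seed + 10_000 if seed is None else seed)

    if n == model.n_train:
        cond_df = model.train_conditioning.copy()
    else:
        idx = rng.integers(0, model.n_train, size=n)
        cond_df = model.train_conditioning.iloc[idx].reset_index(drop=True)
    for key, value in conditions.items():
        cond_df[key] = value

    spec_by_name = {s.name: s for s in _internal_specs(model.schema)}
    cond_enc = (
        np.hstack(
            [
                _encode_column(cond_df, spec_by_name[name], model.cont_stats)
                for name in model.config.conditioning_vars
            ]
        )
        if n > 0
        else np.zeros((0, model.cond_blocks.width))
    )

    tau = model.config.temperature
    z = rng.normal(size=(n, model.config.latent_dim))
    fake = np.zeros((n, model.gen_blocks.width))
    decoded: dict[str, np.ndarray] = {}
    for gv in model.gen_vars:
        parts = [z]
        for c in gv.context:
            if c in model.cond_blocks.slices:
                parts.append(cond_enc[:, model.cond_blocks.slices[c]])
            else:
                parts.append(fake[:, model.gen_blocks.slices[c]])
        raw = gv.head.forward(np.hstack(parts)) if n > 0 else np.zeros((0, gv.out_dim))
        if gv.kind == "continuous":
            mean, std = model.cont_stats[gv.name]
            lo, hi = model.cont_bounds[gv.name]
            span = hi - lo
            slack = model.config.domain_slack * span
            vals = np.clip(raw[:, 0] * std + mean, lo - slack, hi + slack)
            decoded[gv.name] = vals
            fake[:, gv.slice] = raw
        elif gv.kind == "binary":
            g = rng.logistic(size=raw.shape)
            hard = (raw + g > 0).astype(int)[:, 0]
            decoded[gv.name] = hard
            fake[:, gv.slice] = hard[:, None].astype(float)
        else:
            g = rng.gumbel(size=raw.shape)
            choice = np.argmax(raw + g, axis=1) if n > 0 else np.array([], dtype=int)
            decoded[gv.name] = np.array([gv.levels[i] for i in choice], dtype=object)
            onehot = np.zeros_like(raw)
            if n > 0:
                onehot[np.arange(n), choice] = 1.0
            fake[:, gv.slice] = onehot

    df = pd.DataFrame(index=range(n))
    for s in model.schema:
        if s.name in model.config.conditioning_vars:
            df[s.name] = cond_df[s.name].to_numpy()
        elif s.name == "recanalization":
            recan = np.where(decoded["recanalization"] == 1, "complete", "not_complete").astype(object)
            recan[decoded["recan_observed"] == 0] = None
            df[s.name] = recan
        else:
            df[s.name] = decoded[s.name]

    # schema-consistency post-processing
    if "age" in df:
        df["age"] = np.maximum(df["age"].to_numpy(dtype=float), 18.0)
    if "follow_up" in df:
        df["follow_up"] = np.maximum(df["follow_up"].to_numpy(dtype=float), 0.0)
    for lab in ("hemoglobin", "platelets", "d_dimer"):
        if lab in df:
            df[lab] = np.maximum(df[lab].to_numpy(dtype=float), 1e-6)
    if {"ttr", "treatment"} <= set(df.columns):
        ttr = np.clip(df["ttr"].to_numpy(dtype=float), 0.0, 100.0)
        ttr[(df["treatment"] != "VKA").to_numpy()] = np.nan
        df["ttr"] = ttr
    if {"doac_agent", "treatment"} <= set(df.columns):
        agent = df["doac_agent"].to_numpy(dtype=object)
        agent[(df["treatment"] != "DOAC").to_numpy()] = None
        df["doac_agent"] = agent

    return Cohort(df, list(model.schema), label="digital-twin")


def replicate_twins(
    cohort: Cohort,
    dag: DAGSpec | None = None,
    config: GANConfig | None = None,
    n_replicas: int = 10,
    seed_base: int = 0,
) -> list[Cohort]:
    """Train and generate *n_replicas* independent 1:1 twin cohorts.

    Replica *i* trains and generates under the deterministic seed
    ``seed_base + i`` — distinct but controlled seeds, so every replica is
    individually reproducible.
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    config = config or GANConfig()
    cohorts = []
    for i in range(n_replicas):
        cfg = replace(config, seed=seed_base + i)
        model = train_cgan(cohort, dag, cfg)
        twins = generate_twins(model, len(cohort))
        twins.label = f"twin-replica-{i}"
        cohorts.append(twins)
    return cohorts
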