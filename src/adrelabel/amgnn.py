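"""Auto-metric graph neural network for few-shot diagnosis classification.

The classifier operates on episodes (meta-tasks): a small batch of
participants in which a few labelled *support* cases per class are
given and the remaining *query* cases are to be classified.  Edges of
the episode graph are not fixed: a small trainable similarity network
maps the elementwise absolute difference of two participants'
sociodemographic graph features (gender, age, education, parental
family history by default) to a non-negative edge weight — the
"auto-metric".  Each of the two GNN layers builds its own
row-normalized weight matrix, aggregates neighbour representations by
weighted mean, and applies an affine map with a pointwise nonlinearity;
the similarity networks contribute two transform layers each, i.e. four
convolutional layers in total.  Training samples one episode per
iteration from the training split and minimizes cross-entropy on the
query nodes; testing uses one-shot episodes (a single support per
class) whose queries come from the held-out split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from .autodiff import Adam, Tensor, cross_entropy, parameter, softmax_rows
from .relabel import welch_t_test
from .tables import DIAGNOSES, FeatureTable, LabelSet

logger = logging.getLogger(__name__)

__all__ = [
    "AmgnnConfig",
    "Episode",
    "AMGNNClassifier",
    "AMGNNResults",
    "PairedExperimentResult",
    "split_train_test",
    "sample_episode",
    "init_params",
    "build_graph",
    "forward",
    "train",
    "evaluate",
    "run_experiment",
]

DEFAULT_GRAPH_FEATURES = (
    "gender", "age", "education", "mother_ad_history", "father_ad_history",
)


@dataclass
class AmgnnConfig:
    graph_features: tuple = DEFAULT_GRAPH_FEATURES
    n_classes: int = 3
    iterations: int = 300
    batch_size: int = 64
    train_fraction: float = 0.8
    gnn_layers: int = 2
    conv_layers_total: int = 4
    support_per_class: int = 5       # during episodic training
    support_per_class_test: int = 1  # one-shot evaluation
    eval_passes: int = 3             # one-shot coverages of the test pool
    hidden_dim: int = 48
    sim_hidden: int = 16
    learning_rate: float = 1e-3
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly in (0, 1)")
        if self.batch_size < self.n_classes * self.support_per_class + 1:
            raise ValueError(
                "batch_size must allow at least one query beyond the supports")
        if self.gnn_layers != 2 or self.conv_layers_total != 4:
            raise ValueError(
                "this architecture realizes exactly 2 GNN layers whose "
                "similarity networks contribute 4 transform layers")


@dataclass
class Episode:
    """One meta-task: support nodes with known labels plus query nodes."""

    node_features: np.ndarray   # batch x d, full preprocessed features
    graph_features: np.ndarray  # batch x g, the edge-construction subset
    labels: np.ndarray          # batch ints in 0..n_classes-1 (query truth)
    support_mask: np.ndarray    # bool
    query_mask: np.ndarray      # bool
    sample_ids: np.ndarray

    def __post_init__(self) -> None:
        if (self.support_mask & self.query_mask).any():
            raise ValueError("support and query sets must be disjoint")
        support_classes = set(self.labels[self.support_mask].tolist())
        if len(support_classes) < len(set(self.labels.tolist())):
            missing = set(self.labels.tolist()) - support_classes
            raise ValueError(f"classes {missing} absent from the support set")


class EpisodeError(ValueError):
    pass


def split_train_test(table: FeatureTable, labels: LabelSet,
                     train_fraction: float = 0.8,
                     seed: int = 0) -> tuple[pd.Index, pd.Index]:
    """Deterministic stratified split into train/test sample-id sets."""
    from sklearn.model_selection import train_test_split

    counts = labels.labels.value_counts()
    if (counts < 2).any():
        raise ValueError(
            f"stratification impossible: classes with < 2 samples: "
            f"{counts[counts < 2].to_dict()}")
    ids = labels.labels.index.to_numpy()
    train_ids, test_ids = train_test_split(
        ids, train_size=train_fraction, random_state=seed,
        stratify=labels.labels.to_numpy())
    return pd.Index(np.sort(train_ids)), pd.Index(np.sort(test_ids))


def _class_codes(values: pd.Series) -> np.ndarray:
    lookup = {c: i for i, c in enumerate(DIAGNOSES)}
    return np.array([lookup[v] for v in values])


def sample_episode(table: FeatureTable, labels: LabelSet, config: AmgnnConfig,
                   pool: pd.Index, rng: np.random.Generator,
                   mode: str = "train", train_pool: pd.Index | None = None,
                   query_ids: pd.Index | None = None,
                   query_labels: pd.Series | None = None) -> Episode:
    """Draw one meta-task.

    Train mode: supports and queries both come from ``pool``.  Test
    mode: supports come from ``train_pool`` (one per class by default)
    and queries from ``pool`` (or the explicit ``query_ids``), so no
    held-out sample ever leaks into the support set.  ``query_labels``
    optionally overrides the ground truth recorded for the queries
    (used when scoring against latent truth).
    """
    spc = config.support_per_class if mode == "train" else config.support_per_class_test
    support_source = pool if mode == "train" else train_pool
    if support_source is None:
        raise EpisodeError("test-mode episodes need a training pool for supports")
    by_class = labels.labels.loc[support_source].groupby(
        labels.labels.loc[support_source]).groups
    supports = []
    for c in DIAGNOSES:
        members = np.asarray(by_class.get(c, pd.Index([])))
        if len(members) < spc:
            raise EpisodeError(
                f"class {c} has {len(members)} pool members, needs {spc} supports")
        supports.extend(rng.choice(members, size=spc, replace=False))
    supports = pd.Index(supports)

    if query_ids is None:
        n_queries = config.batch_size - len(supports)
        candidates = pool.difference(supports)
        if len(candidates) == 0:
            raise EpisodeError("no query candidates left in the pool")
        n_queries = min(n_queries, len(candidates))
        # class-balanced query draw: equal per-class quotas (remainders and
        # exhausted classes fall back to the remaining pool at random)
        cand_labels = labels.labels.loc[candidates]
        per_class = n_queries // len(DIAGNOSES)
        chosen: list = []
        for c in DIAGNOSES:
            members = np.asarray(cand_labels.index[cand_labels == c])
            take = min(per_class, len(members))
            chosen.extend(rng.choice(members, size=take, replace=False))
        rest = np.asarray(candidates.difference(pd.Index(chosen)))
        fill = n_queries - len(chosen)
        if fill > 0 and len(rest):
            chosen.extend(rng.choice(rest, size=min(fill, len(rest)),
                                     replace=False))
        query_ids = pd.Index(chosen)
    ids = supports.append(pd.Index(query_ids))

    truth = labels.labels.loc[ids].copy()
    if query_labels is not None:
        truth.loc[query_ids] = query_labels.loc[query_ids]
    node_x = table.df.loc[ids].to_numpy(dtype=float)
    graph_x = table.df.loc[ids, list(config.graph_features)].to_numpy(dtype=float)
    n = len(ids)
    support_mask = np.zeros(n, dtype=bool)
    support_mask[: len(supports)] = True
    return Episode(
        node_features=node_x,
        graph_features=graph_x,
        labels=_class_codes(truth),
        support_mask=support_mask,
        query_mask=~support_mask,
        sample_ids=np.asarray(ids),
    )


# ---------------------------------------------------------------------------
# parameters and forward pass
# ---------------------------------------------------------------------------

def init_params(config: AmgnnConfig, n_features: int,
                rng: np.random.Generator) -> dict[str, Tensor]:
    """Initialize the similarity networks and GNN affine maps.

    The similarity networks start as monotonically decreasing functions
    of the feature difference (non-negative first layer, non-positive
    second layer), so identical nodes begin with the largest edge
    weight; training is free to reshape the metric.
    """
    g = len(config.graph_features)
    d_in = n_features + config.n_classes  # features + (one-hot | uniform) label
    h, sh = config.hidden_dim, config.sim_hidden

    def normal(*shape, scale):
        return parameter(rng.normal(0.0, scale, size=shape))

    params = {
        # similarity network of GNN layer 1 (2 transform layers)
        "sim1_w1": parameter(np.abs(rng.normal(0.0, 0.8, size=(g, sh)))),
        "sim1_b1": parameter(np.zeros(sh)),
        "sim1_w2": parameter(-np.abs(rng.normal(0.0, 0.8, size=(sh, 1)))),
        "sim1_b2": parameter(np.ones(1)),
        # similarity network of GNN layer 2
        "sim2_w1": parameter(np.abs(rng.normal(0.0, 0.8, size=(g, sh)))),
        "sim2_b1": parameter(np.zeros(sh)),
        "sim2_w2": parameter(-np.abs(rng.normal(0.0, 0.8, size=(sh, 1)))),
        "sim2_b2": parameter(np.ones(1)),
        # node-update affine maps: a self transform plus a transform of the
        # auto-metric neighbourhood aggregate
        "w1_self": normal(d_in, h, scale=1.0 / np.sqrt(d_in)),
        "w1": normal(d_in, h, scale=1.0 / np.sqrt(d_in)),
        "b1": parameter(np.zeros(h)),
        "w2_self": normal(h, config.n_classes, scale=1.0 / np.sqrt(h)),
        "w2": normal(h, config.n_classes, scale=1.0 / np.sqrt(h)),
        "b2": parameter(np.zeros(config.n_classes)),
    }
    return params


def _pairwise_absdiff(graph_x: np.ndarray) -> np.ndarray:
    return np.abs(graph_x[:, None, :] - graph_x[None, :, :])


def build_graph(episode: Episode, params: dict[str, Tensor],
                layer: int = 1) -> Tensor:
    """Row-normalized learned edge-weight matrix for one GNN layer.

    weight(i, j) = softplus(MLP(|g_i - g_j|)) >= 0, self-edges included
    (the zero difference vector), rows normalized to sum to one.
    """
    if not np.isfinite(episode.graph_features).all():
        raise ValueError("graph features must be finite")
    n = len(episode.sample_ids)
    diffs = _pairwise_absdiff(episode.graph_features).reshape(n * n, -1)
    e = Tensor(diffs)
    w1, b1 = params[f"sim{layer}_w1"], params[f"sim{layer}_b1"]
    w2, b2 = params[f"sim{layer}_w2"], params[f"sim{layer}_b2"]
    raw = ((e @ w1 + b1).relu() @ w2 + b2).softplus().reshape(n, n)
    return raw / raw.sum(axis=1, keepdims=True)


def forward(episode: Episode, params: dict[str, Tensor],
            n_classes: int = 3) -> tuple[np.ndarray, Tensor]:
    """Class probabilities for every node (use the query rows).

    Node representations concatenate the full feature vector with the
    support's one-hot label (queries get a uniform placeholder); two
    rounds of graph construction, weighted-mean aggregation, and affine
    + nonlinearity follow; the final scores are softmax-normalized.
    """
    n = len(episode.sample_ids)
    onehot = np.full((n, n_classes), 1.0 / n_classes)
    sup = episode.support_mask
    onehot[sup] = 0.0
    onehot[sup, episode.labels[sup]] = 1.0
    h0 = Tensor(np.concatenate([episode.node_features, onehot], axis=1))

    a1 = build_graph(episode, params, layer=1)
    h1 = (h0 @ params["w1_self"] + a1 @ h0 @ params["w1"] + params["b1"]).relu()
    a2 = build_graph(episode, params, layer=2)
    logits = h1 @ params["w2_self"] + a2 @ h1 @ params["w2"] + params["b2"]
    return softmax_rows(logits.data), logits


# ---------------------------------------------------------------------------
# training / evaluation
# ---------------------------------------------------------------------------

class TrainingError(RuntimeError):
    pass


def train(table: FeatureTable, labels: LabelSet, train_pool: pd.Index,
          config: AmgnnConfig, seed: int | None = None
          ) -> tuple[dict[str, Tensor], pd.DataFrame]:
    """Episodic training: one meta-task and one optimizer step per iteration.

    Returns the trained parameters and a per-iteration log (loss plus
    query macro AUC / balanced accuracy on that episode).
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    params = init_params(config, n_features=len(table.feature_names), rng=rng)
    opt = Adam(list(params.values()), lr=config.learning_rate)
    log_rows = []
    for it in range(config.iterations):
        episode = sample_episode(table, labels, config, pool=train_pool, rng=rng)
        probs, logits = forward(episode, params, n_classes=config.n_classes)
        loss = cross_entropy(logits, episode.labels, mask=episode.query_mask)
        if not np.isfinite(loss.data):
            raise TrainingError(f"non-finite loss at iteration {it + 1}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        q = episode.query_mask
        truth = np.array(DIAGNOSES)[episode.labels[q]]
        try:
            auc, _ = metrics_mod.macro_auc(probs[q], truth, DIAGNOSES)
        except metrics_mod.UndefinedMetricError:
            auc = np.nan
        bacc = metrics_mod.balanced_accuracy(
            np.array(DIAGNOSES)[probs[q].argmax(axis=1)], truth)
        log_rows.append({"iteration": it + 1, "loss": float(loss.data),
                         "macro_auc": auc, "balanced_accuracy": bacc})
    return params, pd.DataFrame(
        log_rows, columns=["iteration", "loss", "macro_auc", "balanced_accuracy"])


def evaluate(params: dict[str, Tensor], table: FeatureTable, labels: LabelSet,
             test_pool: pd.Index, train_pool: pd.Index, config: AmgnnConfig,
             seed: int = 0, eval_labels: LabelSet | None = None
             ) -> metrics_mod.MetricsReport:
    """One-shot evaluation covering every held-out sample at least once.

    The test pool is chunked into episodes whose supports are drawn from
    the training pool; ``config.eval_passes`` independent coverages are
    run and each sample's class scores are averaged across passes, which
    damps the support-draw noise of single one-shot episodes.
    ``eval_labels`` optionally supplies the ground truth the queries are
    scored against (the supports always carry the labels the model was
    trained with).
    """
    if len(test_pool) == 0:
        raise ValueError("empty test pool")
    rng = np.random.default_rng(seed)
    chunk = config.batch_size - config.n_classes * config.support_per_class_test
    truth_series = (eval_labels.labels if eval_labels is not None
                    else labels.labels)
    prob_sums = pd.DataFrame(0.0, index=test_pool, columns=list(DIAGNOSES))
    counts = pd.Series(0, index=test_pool)
    for _ in range(max(config.eval_passes, 1)):
        order = rng.permutation(np.asarray(test_pool))
        for start in range(0, len(order), chunk):
            qids = pd.Index(order[start: start + chunk])
            episode = sample_episode(
                table, labels, config, pool=test_pool, rng=rng, mode="test",
                train_pool=train_pool, query_ids=qids, query_labels=truth_series)
            probs, _ = forward(episode, params, n_classes=config.n_classes)
            q = episode.query_mask
            prob_sums.loc[episode.sample_ids[q]] += probs[q]
            counts.loc[episode.sample_ids[q]] += 1
    probs = (prob_sums.to_numpy() / counts.to_numpy()[:, None])
    truth = truth_series.loc[test_pool].to_numpy()
    macro, per_class = metrics_mod.macro_auc(probs, truth, DIAGNOSES)
    bacc = metrics_mod.balanced_accuracy(
        np.array(DIAGNOSES)[probs.argmax(axis=1)], truth)
    return metrics_mod.MetricsReport(
        per_class_auc=per_class, macro_auc=macro, balanced_accuracy=bacc)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class AMGNNClassifier:
    """Episodically trained auto-metric GNN bound to a table and labels."""

    def __init__(self, table: FeatureTable, labels: LabelSet,
                 config: AmgnnConfig | None = None):
        if len(labels) != table.n_samples:
            raise ValueError("labels and table must cover the same samples")
        self.table = table
        self.labels = labels
        self.config = config or AmgnnConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str = "diagnosis",
                       config: AmgnnConfig | None = None) -> "AMGNNClassifier":
        labels = LabelSet(df[label_column])
        feats = df.drop(columns=[label_column])
        table = FeatureTable(feats, {c: "cfa" for c in feats.columns},
                             {c: "numeric" for c in feats.columns})
        return cls(table, labels, config)

    def fit(self, seed: int | None = None) -> "AMGNNResults":
        seed = self.config.seed if seed is None else seed
        train_pool, test_pool = split_train_test(
            self.table, self.labels, self.config.train_fraction, seed=seed)
        params, log = train(self.table, self.labels, train_pool,
                            self.config, seed=seed)
        return AMGNNResults(self, params, log, train_pool, test_pool, seed)


@dataclass
class AMGNNResults:
    """Fitted AMGNN: parameters, training log, and the data split."""

    model: AMGNNClassifier
    params: dict[str, Tensor]
    training_log: pd.DataFrame
    train_pool: pd.Index
    test_pool: pd.Index
    seed: int
    _report: metrics_mod.MetricsReport | None = field(default=None, repr=False)

    def evaluate(self, eval_labels: LabelSet | None = None
                 ) -> metrics_mod.MetricsReport:
        report = evaluate(self.params, self.model.table, self.model.labels,
                          self.test_pool, self.train_pool, self.model.config,
                          seed=self.seed, eval_labels=eval_labels)
        self._report = report
        return report

    def summary(self) -> str:
        report = self._report or self.evaluate()
        lines = [
            "Auto-metric GNN results",
            "=" * 45,
            f"training samples     {len(self.train_pool):>6d}",
            f"test samples         {len(self.test_pool):>6d}",
            f"iterations           {self.model.config.iterations:>6d}",
            f"final training loss  {self.training_log['loss'].iloc[-1]:>9.4f}"
            if len(self.training_log) else "final training loss       n/a",
            "-" * 45,
            f"macro one-vs-all AUC {report.macro_auc:>9.4f}",
            f"balanced accuracy    {report.balanced_accuracy:>9.4f}",
        ]
        for c, v in report.per_class_auc.items():
            lines.append(f"  AUC {c:<16} {v:>9.4f}")
        return "\n".join(lines)


@dataclass
class PairedExperimentResult:
    """Repeated paired comparison of two labelings of the same table."""

    original: metrics_mod.MetricsReport
    relabelled: metrics_mod.MetricsReport
    per_repeat: pd.DataFrame
    comparison: dict

    def summary(self) -> str:
        c = self.comparison
        lines = [
            "Paired AMGNN experiment (relabelled vs original labels)",
            "=" * 58,
            f"repeats                     {len(self.per_repeat):>6d}",
            f"macro AUC, original         {self.original.macro_auc:.4f} "
            f"+/- {getattr(self.original, 'macro_auc_sd', float('nan')):.4f}",
            f"macro AUC, relabelled       {self.relabelled.macro_auc:.4f} "
            f"+/- {getattr(self.relabelled, 'macro_auc_sd', float('nan')):.4f}",
            f"balanced acc, original      {self.original.balanced_accuracy:.4f}",
            f"balanced acc, relabelled    {self.relabelled.balanced_accuracy:.4f}",
            f"mean AUC difference         {c['mean_difference']:+.4f}",
            f"relabelled wins             {c['relabelled_wins']}/{len(self.per_repeat)}",
        ]
        if "p_value" in c:
            lines.append(f"two-sided t-test            t = {c['t_statistic']:.3f}, "
                         f"p = {c['p_value']:.4f}")
        return "\n".join(lines)


def run_experiment(table: FeatureTable, labels_original: LabelSet,
                   labels_relabelled: LabelSet, config: AmgnnConfig | None = None,
                   n_repeats: int = 30, eval_labels: LabelSet | None = None,
                   base_seed: int = 0) -> PairedExperimentResult:
    """Train/evaluate both labelings on identical fresh splits, repeatedly.

    Repeat r uses seed ``base_seed + r`` for its split, episode sampling
    and initialization.  Queries are scored against ``eval_labels`` when
    given (e.g. latent truth on synthetic data), otherwise against the
    labeling each arm was trained with.
    """
    if len(labels_original) != len(labels_relabelled):
        raise ValueError("label sets must cover the same samples")
    config = config or AmgnnConfig()
    reports_o, reports_r, rows = [], [], []
    for r in range(n_repeats):
        seed = base_seed + r
        train_pool, test_pool = split_train_test(
            table, labels_original, config.train_fraction, seed=seed)
        try:
            arm = {}
            for name, labs in (("original", labels_original),
                               ("relabelled", labels_relabelled)):
                params, _ = train(table, labs, train_pool, config, seed=seed)
                arm[name] = evaluate(params, table, labs, test_pool, train_pool,
                                     config, seed=seed, eval_labels=eval_labels)
        except (TrainingError, EpisodeError) as exc:
            raise TrainingError(f"[repeat {r}] {exc}") from exc
        reports_o.append(arm["original"])
        reports_r.append(arm["relabelled"])
        rows.append({
            "repeat": r,
            "auc_original": arm["original"].macro_auc,
            "auc_relabelled": arm["relabelled"].macro_auc,
            "bacc_original": arm["original"].balanced_accuracy,
            "bacc_relabelled": arm["relabelled"].balanced_accuracy,
        })
    per_repeat = pd.DataFrame(rows)
    agg_o = metrics_mod.aggregate_repeats(reports_o)
    agg_r = metrics_mod.aggregate_repeats(reports_r)
    diff = per_repeat["auc_relabelled"] - per_repeat["auc_original"]
    comparison = {
        "mean_difference": float(diff.mean()),
        "relabelled_wins": int((diff > 0).sum()),
    }
    if n_repeats >= 2:
        t, p = welch_t_test(per_repeat["auc_relabelled"],
                            per_repeat["auc_original"])
        comparison.update({"t_statistic": t, "p_value": p})
    return PairedExperimentResult(agg_o, agg_r, per_repeat, comparison)
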