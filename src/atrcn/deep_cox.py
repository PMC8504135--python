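"""Deep Cox proportional-hazards network.

The network is a small fully connected net mapping a sample's feature
vector x to a scalar log relative hazard h(x); under proportional hazards
the conditional hazard is lambda(t|x) = lambda0(t) * exp(h(x)).  Training
minimizes the negative log partial likelihood

    l(theta) = - sum_{i: E_i = 1} [ h(x_i) - log sum_{j in R(T_i)} exp(h(x_j)) ]

where R(T_i) = {j : T_j >= T_i} is the risk set at the i-th event time
(Breslow handling of tied times: every sample still under observation,
including those tied with i, stays in the denominator).  The partial
likelihood couples samples through the risk sets, so optimization is
full-batch by default; forward, backward and the Adam update are written
directly in numpy, which keeps the exact loss and makes gradients easy to
verify against finite differences.

With ``hidden_dims=[]`` the network degenerates to a linear Cox model
h(x) = w.x, useful as a baseline and for recovery checks against data
simulated from a linear risk.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .cohort_io import SurvivalTable

logger = logging.getLogger("atrcn")

CHECKPOINT_VERSION = 1
LEARNING_RATE_GRID = (1e-3, 1e-4, 1e-5)


@dataclass
class NetworkSpec:
    input_dim: int
    hidden_dims: tuple[int, ...] = (50, 20, 10)
    activation: str = "relu"
    dropout: float = 0.0

    def __post_init__(self) -> None:
        self.hidden_dims = tuple(int(h) for h in self.hidden_dims)
        if self.input_dim < 1:
            raise ValueError("input_dim must be >= 1")
        if any(h < 1 for h in self.hidden_dims):
            raise ValueError("hidden dims must all be >= 1")
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")

    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        dims = [self.input_dim, *self.hidden_dims, 1]
        return list(zip(dims[:-1], dims[1:]))


@dataclass
class CoxNetwork:
    spec: NetworkSpec
    weights: list[np.ndarray]   # W_l: (fan_in, fan_out)
    biases: list[np.ndarray]    # b_l: (fan_out,)
    init_seed: int
    loss_trace: list[float] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    def copy(self) -> "CoxNetwork":
        return CoxNetwork(
            self.spec,
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.init_seed,
            list(self.loss_trace),
        )

    def save(self, path: str) -> None:
        payload = {
            "version": CHECKPOINT_VERSION,
            "spec": self.spec,
            "weights": self.weights,
            "biases": self.biases,
            "init_seed": self.init_seed,
            "loss_trace": self.loss_trace,
        }
        with open(path, "wb") as fh:
            pickle.dump(payload, fh)

    @classmethod
    def load(cls, path: str) -> "CoxNetwork":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"checkpoint version {payload.get('version')!r} does not match "
                f"supported version {CHECKPOINT_VERSION}"
            )
        return cls(
            payload["spec"], payload["weights"], payload["biases"],
            payload["init_seed"], payload["loss_trace"],
        )


@dataclass
class TrainingConfig:
    learning_rate: float = 1e-3
    epochs: int = 500
    optimizer: str = "adam"
    l2_penalty: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.l2_penalty < 0:
            raise ValueError("l2 penalty must be >= 0")


@dataclass
class RiskScores:
    sample_ids: list[str]
    score: np.ndarray

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if not np.isfinite(self.score).all():
            raise ValueError("non-finite risk score")


# ---------------------------------------------------------------------------
# initialization and forward pass
# ---------------------------------------------------------------------------

def init_network(spec: NetworkSpec, seed: int = 0) -> CoxNetwork:
    """Glorot-uniform weights, zero biases; reproducible given seed."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in spec.layer_dims:
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return CoxNetwork(spec, weights, biases, seed)


def _forward(net: CoxNetwork, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Return (scores, layer activations); activations[0] is the input."""
    acts = [x]
    h = x
    last = net.n_layers - 1
    for l, (w, b) in enumerate(zip(net.weights, net.biases)):
        h = h @ w + b
        if l < last:
            h = np.maximum(h, 0.0)
        acts.append(h)
    return h[:, 0], acts


def forward_risk(net: CoxNetwork, x: np.ndarray, sample_ids: list[str] | None = None) -> RiskScores:
    """Score samples: one finite log relative hazard h(x) per row of x."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[1] != net.spec.input_dim:
        raise ValueError(
            f"feature matrix has {x.shape[1] if x.ndim == 2 else '?'} columns, "
            f"network expects {net.spec.input_dim}"
        )
    scores, _ = _forward(net, x)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(x.shape[0])]
    return RiskScores(sample_ids, scores)


# ---------------------------------------------------------------------------
# negative log partial likelihood and its gradient
# ---------------------------------------------------------------------------

def _partial_likelihood_terms(
    scores: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, np.ndarray]:
    """Loss and gradient with respect to scores, risk sets {j: T_j >= T_i}.

    Log-sum-exp is stabilized by subtracting the global score maximum (the
    partial likelihood is invariant to a constant shift of all scores).
    """
    n = scores.shape[0]
    shift = scores.max()
    s = scores - shift
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    s_sorted = s[order]
    e_sorted = event[order].astype(bool)

    # suffix log-sum-exp: lse[p] = log sum_{q >= p} exp(s_sorted[q])
    rev_exp = np.exp(s_sorted[::-1])
    lse = np.log(np.cumsum(rev_exp))[::-1]
    # risk-set start index for each position (first index of its tie group)
    start = np.searchsorted(t_sorted, t_sorted, side="left")

    ev_pos = np.flatnonzero(e_sorted)
    loss = float(-(s_sorted[ev_pos] - lse[start[ev_pos]]).sum())

    # gradient: dL/ds_k = -E_k + exp(s_k) * sum_{events i: start_i <= pos_k} exp(-lse_i)
    # overflow here only occurs once training has already diverged; the
    # resulting non-finite loss is caught by the training loop
    with np.errstate(over="ignore", invalid="ignore"):
        add = np.zeros(n + 1)
        np.add.at(add, start[ev_pos], np.exp(-lse[start[ev_pos]]))
        g_cum = np.cumsum(add[:-1])
        grad_sorted = -e_sorted.astype(float) + np.exp(s_sorted) * g_cum
    grad = np.empty(n)
    grad[order] = grad_sorted
    return loss, grad


def cox_loss(
    scores: RiskScores | np.ndarray,
    s: SurvivalTable,
    normalize_by_events: bool = False,
    allow_no_events: bool = False,
) -> float:
    """Negative log partial likelihood of the scores given survival data."""
    vec = scores.score if isinstance(scores, RiskScores) else np.asarray(scores, dtype=float)
    if vec.shape[0] != s.n_samples:
        raise ValueError("scores not aligned with survival table")
    if s.n_events == 0:
        if allow_no_events:
            logger.warning("no uncensored patients: partial likelihood is empty, loss 0")
            return 0.0
        raise ValueError("no uncensored patients in survival table")
    loss, _ = _partial_likelihood_terms(vec, s.time, s.event)
    if normalize_by_events:
        loss /= s.n_events
    return loss


def cox_loss_gradient(scores: np.ndarray, s: SurvivalTable) -> np.ndarray:
    """Analytic gradient of the (unnormalized) loss with respect to scores."""
    if s.n_events == 0:
        return np.zeros_like(scores, dtype=float)
    _, grad = _partial_likelihood_terms(np.asarray(scores, dtype=float), s.time, s.event)
    return grad


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _backward(
    net: CoxNetwork, acts: list[np.ndarray], dscores: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Backpropagate dL/dscores through the relu MLP."""
    dW = [np.empty(0)] * net.n_layers
    db = [np.empty(0)] * net.n_layers
    delta = dscores[:, None]  # (n, 1)
    last = net.n_layers - 1
    for l in range(last, -1, -1):
        a_in = acts[l]
        dW[l] = a_in.T @ delta
        db[l] = delta.sum(axis=0)
        if l > 0:
            delta = delta @ net.weights[l].T
            delta = delta * (acts[l] > 0)  # relu mask (post-activation > 0)
    return dW, db


def network_gradients(
    net: CoxNetwork, groups: list[tuple[np.ndarray, SurvivalTable]]
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """Loss and parameter gradients over cohort groups with stratified risk sets.

    Each (features, survival) group contributes its own partial likelihood;
    losses and gradients sum across groups, so survival times are never
    compared across cohorts.
    """
    total = 0.0
    dW = [np.zeros_like(w) for w in net.weights]
    db = [np.zeros_like(b) for b in net.biases]
    for x, s in groups:
        scores, acts = _forward(net, x)
        loss, dscores = _partial_likelihood_terms(scores, s.time, s.event)
        total += loss
        gW, gb = _backward(net, acts, dscores)
        for l in range(net.n_layers):
            dW[l] += gW[l]
            db[l] += gb[l]
    return total, dW, db


def train_network(
    net: CoxNetwork,
    x: np.ndarray,
    s: SurvivalTable,
    cfg: TrainingConfig,
    freeze_layers: int = 0,
) -> CoxNetwork:
    """Train on a single cohort; returns a new network, input unchanged."""
    return train_network_grouped(net, [(np.asarray(x, dtype=float), s)], cfg, freeze_layers)


def train_network_grouped(
    net: CoxNetwork,
    groups: list[tuple[np.ndarray, SurvivalTable]],
    cfg: TrainingConfig,
    freeze_layers: int = 0,
) -> CoxNetwork:
    """Full-batch Adam on the summed per-group negative log partial likelihoods.

    ``freeze_layers`` leading hidden layers are excluded from the update
    (their gradients are discarded), supporting partial fine-tuning.
    """
    if not groups:
        raise ValueError("no training groups")
    for x, s in groups:
        if x.shape[0] != s.n_samples:
            raise ValueError("features not aligned with survival table")
        if x.shape[1] != net.spec.input_dim:
            raise ValueError("feature dimension does not match network input_dim")
        if s.n_events == 0:
            raise ValueError("a training group has no events")
    if cfg.optimizer != "adam":
        raise ValueError("only the adam optimizer is supported")

    out = net.copy()
    if cfg.epochs == 0:
        return out
    b1, b2, eps = 0.9, 0.999, 1e-8
    mW = [np.zeros_like(w) for w in out.weights]
    vW = [np.zeros_like(w) for w in out.weights]
    mb = [np.zeros_like(b) for b in out.biases]
    vb = [np.zeros_like(b) for b in out.biases]
    trainable = list(range(freeze_layers, out.n_layers))

    for epoch in range(1, cfg.epochs + 1):
        loss, dW, db = network_gradients(out, groups)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch} "
                f"(lr={cfg.learning_rate}); reduce the learning rate"
            )
        if cfg.l2_penalty > 0:
            for l in trainable:
                loss += cfg.l2_penalty * float((out.weights[l] ** 2).sum())
                dW[l] = dW[l] + 2.0 * cfg.l2_penalty * out.weights[l]
        out.loss_trace.append(loss)
        corr1 = 1.0 - b1 ** epoch
        corr2 = 1.0 - b2 ** epoch
        for l in trainable:
            mW[l] = b1 * mW[l] + (1 - b1) * dW[l]
            vW[l] = b2 * vW[l] + (1 - b2) * dW[l] ** 2
            out.weights[l] -= cfg.learning_rate * (mW[l] / corr1) / (np.sqrt(vW[l] / corr2) + eps)
            mb[l] = b1 * mb[l] + (1 - b1) * db[l]
            vb[l] = b2 * vb[l] + (1 - b2) * db[l] ** 2
            out.biases[l] -= cfg.learning_rate * (mb[l] / corr1) / (np.sqrt(vb[l] / corr2) + eps)
    return out


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

def cross_validate_hyperparams(
    x: np.ndarray,
    s: SurvivalTable,
    spec: NetworkSpec,
    grid: list[TrainingConfig] | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[TrainingConfig, dict[float, float]]:
    """Pick the training config with the best mean held-out concordance.

    Folds are stratified by event status so every fold contains events.
    Exact ties in mean C break toward the larger learning rate.  Returns
    (best config, {learning_rate: mean C}).
    """
    from .evaluation import concordance_index  # local import: avoid cycle

    if grid is None:
        grid = [TrainingConfig(learning_rate=lr, seed=seed) for lr in LEARNING_RATE_GRID]
    if len(grid) == 1:
        return grid[0], {grid[0].learning_rate: float("nan")}
    x = np.asarray(x, dtype=float)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(x, s.event))
    for _, test_idx in folds:
        if s.event[test_idx].sum() == 0:
            raise ValueError("a CV fold has no events; reduce n_folds")

    mean_c: dict[float, float] = {}
    results: list[tuple[float, float, TrainingConfig]] = []
    for cfg in grid:
        cs = []
        for train_idx, test_idx in folds:
            net = init_network(spec, seed=cfg.seed)
            try:
                fitted = train_network(net, x[train_idx], s.subset(train_idx), cfg)
                scores = forward_risk(fitted, x[test_idx])
                cs.append(concordance_index(scores, s.subset(test_idx)))
            except FloatingPointError:
                cs.append(0.0)  # diverged: worst possible candidate
        c = float(np.mean(cs))
        mean_c[cfg.learning_rate] = c
        results.append((c, cfg.learning_rate, cfg))
    best = max(results, key=lambda r: (r[0], r[1]))
    return best[2], mean_c
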