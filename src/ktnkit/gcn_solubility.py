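"""Structure-conditioned GCN solubility scorer with attention pooling and
additive per-residue attribution.

Architecture (mirroring the GraphSol family of models at desk scale): two
graph-convolution layers

    H^(l+1) = ReLU(D^-1 A H^(l) W^(l)),

where A is the binary residue contact map with self-connections (contact:
C-beta distance <= 8 A, C-alpha for glycine) and D^-1 row-normalizes it; a
self-attention pooling layer with four heads, each scoring nodes with
score_h(i) = v_h . tanh(W_h h_i) and softmax-pooling the hidden vectors;
and a final linear map ("final convolution") + sigmoid onto a solubility
score in (0, 1).

Because the final map is linear in the pooled vector, the pre-sigmoid logit
decomposes additively over residues:

    contribution_i = sum_h alpha_h,i (w_out,h . h_i),
    sum_i contribution_i + bias = logit,

which is the per-residue attribution report.  The sigmoid is monotone, so
the sign of a contribution carries over to the solubility direction.

Node features are laid out in fixed blocks of total width 91:
BLOSUM62 row (20) | PSSM (20) | HMM (30) | physicochemical (7) |
secondary-structure one-hot H/E/C (3) | SASA, min-max scaled per chain (1) |
other sequence-predicted structural features (10).  The evolutionary and
sequence-predicted blocks are zero-filled when (as here) no alignment
pipeline supplies them.

The network is small enough that forward and backward passes are written
directly in numpy; training uses Adam on squared error and is deterministic
given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .structure_metrics import (
    HYDROPHOBIC,
    STANDARD_AA,
    Structure,
    binary_contact_map,
)

logger = logging.getLogger(__name__)

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Feature block layout (start, width)
BLOCKS = {
    "blosum": (0, 20),
    "pssm": (20, 20),
    "hmm": (40, 30),
    "physchem": (70, 7),
    "ss": (77, 3),
    "sasa": (80, 1),
    "struct_other": (81, 10),
}
FEATURE_WIDTH = 91

#: Seven physicochemical descriptors per residue (steric parameter,
#: polarizability, volume, hydrophobicity, isoelectric point, helix and
#: sheet propensity) from the standard Meiler parameterization.
PHYSCHEM = {
    "A": (1.28, 0.05, 1.00, 0.31, 6.11, 0.42, 0.23),
    "C": (1.77, 0.13, 2.43, 1.54, 6.35, 0.17, 0.41),
    "D": (1.60, 0.11, 2.78, -0.77, 2.95, 0.25, 0.20),
    "E": (1.56, 0.15, 3.78, -0.64, 3.09, 0.42, 0.21),
    "F": (2.94, 0.29, 5.89, 1.79, 5.67, 0.30, 0.38),
    "G": (0.00, 0.00, 0.00, 0.00, 6.07, 0.13, 0.15),
    "H": (2.99, 0.23, 4.66, 0.13, 7.69, 0.27, 0.30),
    "I": (4.19, 0.19, 4.00, 1.80, 6.04, 0.30, 0.45),
    "K": (1.89, 0.22, 4.77, -0.99, 9.99, 0.32, 0.27),
    "L": (2.59, 0.19, 4.00, 1.70, 6.04, 0.39, 0.31),
    "M": (2.35, 0.22, 4.43, 1.23, 5.71, 0.38, 0.32),
    "N": (1.60, 0.13, 2.95, -0.60, 6.52, 0.21, 0.22),
    "P": (2.67, 0.00, 2.72, 0.72, 6.80, 0.13, 0.34),
    "Q": (1.56, 0.18, 3.95, -0.22, 5.65, 0.36, 0.25),
    "R": (2.34, 0.29, 6.13, -1.01, 10.74, 0.36, 0.25),
    "S": (1.31, 0.06, 1.60, -0.04, 5.70, 0.20, 0.28),
    "T": (3.03, 0.11, 2.60, 0.26, 5.60, 0.21, 0.36),
    "V": (3.67, 0.14, 3.00, 1.22, 6.02, 0.27, 0.49),
    "W": (3.21, 0.41, 6.13, 2.25, 5.94, 0.32, 0.42),
    "Y": (2.94, 0.30, 6.47, 0.96, 5.66, 0.25, 0.41),
}

_SS_INDEX = {"H": 0, "E": 1, "C": 2}


def _blosum62_rows() -> dict[str, np.ndarray]:
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    rows = {}
    for aa in AA_ORDER:
        rows[aa] = np.array([m[aa, bb] for bb in AA_ORDER], dtype=float) / 10.0
    return rows


_BLOSUM_CACHE: dict[str, np.ndarray] | None = None


def _blosum_row(aa: str) -> np.ndarray:
    global _BLOSUM_CACHE
    if _BLOSUM_CACHE is None:
        _BLOSUM_CACHE = _blosum62_rows()
    return _BLOSUM_CACHE[aa]


@dataclass
class ProteinGraph:
    """Residue graph: feature matrix + binary contact adjacency.

    ``A`` is the 0/1 contact matrix with unit diagonal; ``A_hat`` is the
    row-normalized propagation matrix D^-1 A (degrees are integer row sums,
    so normalization is exact up to one float division per entry).
    """

    sequence: str
    node_features: np.ndarray        # (N, FEATURE_WIDTH)
    A: np.ndarray                    # (N, N) int 0/1
    A_hat: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.A)
        if not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if not np.all(np.diag(A) == 1):
            raise ValueError("adjacency must have self-connections")
        if self.node_features.shape != (len(self.sequence), FEATURE_WIDTH):
            raise ValueError(
                f"feature matrix must be (N, {FEATURE_WIDTH})"
            )
        deg = A.sum(axis=1)
        self.A_hat = A / deg[:, None]

    @property
    def n_nodes(self) -> int:
        return len(self.sequence)


def node_features_for(
    sequence: str,
    sasa_per_residue: np.ndarray | None = None,
    ss_labels: list[str] | None = None,
) -> np.ndarray:
    """Assemble the block feature matrix for a chain.

    SASA is min-max scaled to [0, 1] over the chain; missing SASA or
    secondary structure leaves the block at zero, as do the evolutionary
    blocks (no alignment pipeline here).
    """
    bad = sorted(set(sequence) - STANDARD_AA)
    if bad:
        raise ValueError(f"nonstandard residue letter(s): {bad}")
    n = len(sequence)
    H = np.zeros((n, FEATURE_WIDTH))
    b0, bw = BLOCKS["blosum"]
    p0, _ = BLOCKS["physchem"]
    for i, aa in enumerate(sequence):
        H[i, b0:b0 + bw] = _blosum_row(aa)
        H[i, p0:p0 + 7] = PHYSCHEM[aa]
    # keep physicochemical magnitudes comparable to the other blocks
    H[:, p0:p0 + 7] /= np.array([4.19, 0.41, 6.47, 2.25, 10.74, 1.0, 1.0])
    if ss_labels is not None:
        s0, _ = BLOCKS["ss"]
        for i, lab in enumerate(ss_labels):
            H[i, s0 + _SS_INDEX[collapse_ss(lab)]] = 1.0
    if sasa_per_residue is not None:
        v = np.asarray(sasa_per_residue, dtype=float)
        lo, hi = v.min(), v.max()
        scaled = (v - lo) / (hi - lo) if hi > lo else np.zeros_like(v)
        H[:, BLOCKS["sasa"][0]] = scaled
    return H


def collapse_ss(label: str) -> str:
    """Collapse 8-class DSSP labels to helix/sheet/coil."""
    if label in ("H", "G", "I"):
        return "H"
    if label in ("E", "B"):
        return "E"
    return "C"


def build_protein_graph(
    structure: Structure,
    sasa_per_residue: np.ndarray | None = None,
    ss_labels: list[str] | None = None,
    cutoff: float = 8.0,
) -> ProteinGraph:
    """Residue graph from a structure: features + 8 A binary contact map."""
    A = binary_contact_map(structure, cutoff=cutoff)
    H = node_features_for(
        structure.sequence, sasa_per_residue,
        ss_labels if ss_labels is not None else structure.ss_labels,
    )
    return ProteinGraph(sequence=structure.sequence, node_features=H, A=A)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class Hyperparameters:
    hidden1: int = 64
    hidden2: int = 64
    attn_dim: int = 32
    n_heads: int = 4
    learning_rate: float = 3e-3
    epochs: int = 100
    batch_size: int = 32
    weight_decay: float = 1e-4       # L2 on weight matrices, not the bias
    n_ensemble: int = 3              # independently initialized nets averaged


@dataclass
class SolubilityModel:
    """Weights of the 2-layer GCN + 4-head attention pooling + linear/sigmoid."""

    W0: np.ndarray                   # (F, h1)
    W1: np.ndarray                   # (h1, h2)
    Wa: np.ndarray                   # (heads, attn_dim, h2)
    va: np.ndarray                   # (heads, attn_dim)
    w_out: np.ndarray                # (heads * h2,)
    bias: float
    seed: int | None = None

    @property
    def n_heads(self) -> int:
        return self.Wa.shape[0]

    @classmethod
    def initialize(
        cls, hp: Hyperparameters | None = None, seed: int = 0,
        feature_width: int = FEATURE_WIDTH,
    ) -> "SolubilityModel":
        hp = hp or Hyperparameters()
        rng = np.random.default_rng(seed)

        def glorot(*shape):
            fan = shape[-2] + shape[-1] if len(shape) >= 2 else shape[-1] + 1
            return rng.uniform(-1, 1, size=shape) * np.sqrt(6.0 / fan)

        return cls(
            W0=glorot(feature_width, hp.hidden1),
            W1=glorot(hp.hidden1, hp.hidden2),
            Wa=glorot(hp.n_heads, hp.attn_dim, hp.hidden2),
            va=glorot(hp.n_heads, hp.attn_dim),
            w_out=glorot(hp.n_heads * hp.hidden2) * 0.1,
            bias=0.0,
            seed=seed,
        )

    def save(self, path) -> None:
        np.savez(path, W0=self.W0, W1=self.W1, Wa=self.Wa, va=self.va,
                 w_out=self.w_out, bias=self.bias)

    @classmethod
    def load(cls, path) -> "SolubilityModel":
        z = np.load(path)
        return cls(W0=z["W0"], W1=z["W1"], Wa=z["Wa"], va=z["va"],
                   w_out=z["w_out"], bias=float(z["bias"]))


@dataclass
class SolubilityEnsemble:
    """Average of independently initialized nets of identical architecture.

    The ensemble's pre-sigmoid logit is the mean of the members' logits, so
    per-residue attribution stays exactly additive (contributions and bias
    are member means).  Averaging over a few random initializations removes
    most of the seed-to-seed variance of a single training run.
    """

    members: list[SolubilityModel]
    seed: int | None = None

    @property
    def bias(self) -> float:
        return float(np.mean([m.bias for m in self.members]))

    def save(self, path) -> None:
        arrays: dict[str, np.ndarray] = {"n_members": np.array(len(self.members))}
        for i, m in enumerate(self.members):
            for k in ("W0", "W1", "Wa", "va", "w_out"):
                arrays[f"{k}_{i}"] = getattr(m, k)
            arrays[f"bias_{i}"] = np.array(m.bias)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "SolubilityEnsemble":
        z = np.load(path)
        n = int(z["n_members"])
        return cls(members=[
            SolubilityModel(
                W0=z[f"W0_{i}"], W1=z[f"W1_{i}"], Wa=z[f"Wa_{i}"],
                va=z[f"va_{i}"], w_out=z[f"w_out_{i}"],
                bias=float(z[f"bias_{i}"]),
            )
            for i in range(n)
        ])


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x)) if x >= 0 else np.exp(x) / (1.0 + np.exp(x))


def _forward(graph: ProteinGraph, model: SolubilityModel) -> dict:
    M = graph.A_hat
    X = graph.node_features
    Z0 = M @ X @ model.W0
    H1 = np.maximum(Z0, 0.0)
    Z1 = M @ H1 @ model.W1
    H2 = np.maximum(Z1, 0.0)
    heads = model.n_heads
    h2 = H2.shape[1]
    T = np.tanh(np.einsum("hdk,nk->hnd", model.Wa, H2))       # (heads, N, da)
    s = np.einsum("hnd,hd->hn", T, model.va)                  # (heads, N)
    s = s - s.max(axis=1, keepdims=True)
    e = np.exp(s)
    alpha = e / e.sum(axis=1, keepdims=True)                  # (heads, N)
    g_heads = np.einsum("hn,nk->hk", alpha, H2)               # (heads, h2)
    g = g_heads.reshape(heads * h2)
    logit = float(model.w_out @ g + model.bias)
    return {
        "M": M, "X": X, "Z0": Z0, "H1": H1, "Z1": Z1, "H2": H2,
        "T": T, "alpha": alpha, "g": g, "logit": logit,
        "score": _sigmoid(logit),
    }


def gcn_forward(
    graph: ProteinGraph, model: "SolubilityModel | SolubilityEnsemble"
) -> tuple[float, dict]:
    """Predicted solubility in (0, 1) and the hidden states of the pass.

    For an ensemble the score is the sigmoid of the mean member logit and
    the returned dict carries the per-member caches under ``"members"``.
    """
    if isinstance(model, SolubilityEnsemble):
        caches = [_forward(graph, m) for m in model.members]
        logit = float(np.mean([c["logit"] for c in caches]))
        return _sigmoid(logit), {"logit": logit, "members": caches}
    cache = _forward(graph, model)
    return cache["score"], cache


@dataclass
class AttributionReport:
    """Signed per-residue contributions to the pre-sigmoid logit.

    contributions sum to (logit - bias) exactly by construction; the model
    bias is reported separately.
    """

    contributions: np.ndarray        # (N,)
    logit: float
    bias: float
    score: float

    def ranked(self) -> list[tuple[int, float]]:
        order = np.argsort(self.contributions)
        return [(int(i) + 1, float(self.contributions[i])) for i in order]


def residue_attribution(
    graph: ProteinGraph, model: "SolubilityModel | SolubilityEnsemble"
) -> AttributionReport:
    """Per-residue additive decomposition of the pre-sigmoid logit."""
    if isinstance(model, SolubilityEnsemble):
        reports = [residue_attribution(graph, m) for m in model.members]
        contrib = np.mean([r.contributions for r in reports], axis=0)
        logit = float(np.mean([r.logit for r in reports]))
        return AttributionReport(
            contributions=contrib, logit=logit, bias=model.bias,
            score=_sigmoid(logit),
        )
    cache = _forward(graph, model)
    H2, alpha = cache["H2"], cache["alpha"]
    heads = model.n_heads
    h2 = H2.shape[1]
    w_blocks = model.w_out.reshape(heads, h2)
    # contribution_i = sum_h alpha_h,i * (w_out,h . h2_i)
    proj = H2 @ w_blocks.T                                    # (N, heads)
    contrib = (alpha.T * proj).sum(axis=1)
    return AttributionReport(
        contributions=contrib, logit=cache["logit"], bias=model.bias,
        score=cache["score"],
    )


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _backward(
    cache: dict, model: SolubilityModel, dlogit: float
) -> dict[str, np.ndarray]:
    M, X = cache["M"], cache["X"]
    Z0, H1, Z1, H2 = cache["Z0"], cache["H1"], cache["Z1"], cache["H2"]
    T, alpha, g = cache["T"], cache["alpha"], cache["g"]
    heads = model.n_heads
    h2 = H2.shape[1]

    grads = {"w_out": dlogit * g, "bias": np.array(dlogit)}
    dg = dlogit * model.w_out.reshape(heads, h2)              # (heads, h2)
    dH2 = np.einsum("hn,hk->nk", alpha, dg)
    dalpha = np.einsum("nk,hk->hn", H2, dg)                   # (heads, N)
    inner = (alpha * dalpha).sum(axis=1, keepdims=True)
    ds = alpha * (dalpha - inner)                             # softmax jac
    grads["va"] = np.einsum("hnd,hn->hd", T, ds)
    dT = np.einsum("hn,hd->hnd", ds, model.va)
    dpre = dT * (1.0 - T ** 2)
    grads["Wa"] = np.einsum("hnd,nk->hdk", dpre, H2)
    dH2 += np.einsum("hnd,hdk->nk", dpre, model.Wa)

    dZ1 = dH2 * (Z1 > 0)
    grads["W1"] = (M @ H1).T @ dZ1
    dH1 = M.T @ dZ1 @ model.W1.T
    dZ0 = dH1 * (Z0 > 0)
    grads["W0"] = (M @ X).T @ dZ0
    return grads


def train(
    dataset: list[tuple[ProteinGraph, float]],
    hp: Hyperparameters | None = None,
    seed: int = 0,
) -> tuple["SolubilityModel | SolubilityEnsemble", list[float]]:
    """Fit the model to (graph, solubility) pairs by Adam on squared error.

    Trains ``hp.n_ensemble`` independently initialized nets (seeds derived
    from ``seed``) and returns their logit-averaging ensemble, or the single
    net when ``n_ensemble`` is 1.  Deterministic for a given seed
    (initialization and shuffling both draw from it).  The returned curve is
    the per-epoch mean-squared error, averaged over members.  Raises if the
    loss diverges to NaN.
    """
    hp = hp or Hyperparameters()
    if hp.n_ensemble > 1:
        members, curves = [], []
        for k in range(hp.n_ensemble):
            m, c = train(
                dataset,
                Hyperparameters(**{**hp.__dict__, "n_ensemble": 1}),
                seed=seed + 7919 * k,
            )
            members.append(m)
            curves.append(c)
        ensemble = SolubilityEnsemble(members=members, seed=seed)
        return ensemble, list(np.mean(curves, axis=0))
    if len(dataset) < 50:
        raise ValueError("need at least 50 graphs to train")
    model = SolubilityModel.initialize(hp, seed=seed)
    rng = np.random.default_rng(seed + 1)

    params = {"W0": model.W0, "W1": model.W1, "Wa": model.Wa,
              "va": model.va, "w_out": model.w_out,
              "bias": np.array(model.bias)}
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(p) for k, p in params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    curve: list[float] = []
    idx = np.arange(len(dataset))
    for epoch in range(hp.epochs):
        rng.shuffle(idx)
        total = 0.0
        for start in range(0, len(idx), hp.batch_size):
            batch = idx[start:start + hp.batch_size]
            acc = {k: np.zeros_like(p) for k, p in params.items()}
            for i in batch:
                graph, y = dataset[i]
                cache = _forward(graph, model)
                err = cache["score"] - y
                total += err * err
                p = cache["score"]
                dlogit = 2.0 * err * p * (1.0 - p)
                g = _backward(cache, model, dlogit)
                for k in acc:
                    acc[k] += g[k]
            step += 1
            for k in params:
                gk = acc[k] / len(batch)
                if k != "bias" and hp.weight_decay > 0:
                    gk = gk + hp.weight_decay * params[k]
                m[k] = b1 * m[k] + (1 - b1) * gk
                v[k] = b2 * v[k] + (1 - b2) * gk * gk
                mhat = m[k] / (1 - b1 ** step)
                vhat = v[k] / (1 - b2 ** step)
                params[k] -= hp.learning_rate * mhat / (np.sqrt(vhat) + eps)
            model.bias = float(params["bias"])
        mse = total / len(idx)
        if not np.isfinite(mse):
            raise RuntimeError(
                "training diverged (loss is NaN); lower the learning rate"
            )
        curve.append(mse)
    model.seed = seed
    return model, curve


def r_squared(
    model: SolubilityModel, dataset: list[tuple[ProteinGraph, float]]
) -> float:
    """Coefficient of determination of predictions against labels."""
    y = np.array([lab for _, lab in dataset])
    yhat = np.array([gcn_forward(g, model)[0] for g, _ in dataset])
    ss_res = ((y - yhat) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return float(1.0 - ss_res / ss_tot)
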