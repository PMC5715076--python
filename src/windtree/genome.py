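"""Genome encoding, growth-policy neural networks, and mutation.

A genome is 34 genes in ``[0, 1]``: 3 branching-angle genes, 18 genes for the
primary-growth network (2 inputs, 3 hidden neurons, 3 outputs), 10 genes for
the secondary-growth network (2 inputs, 3 hidden neurons, 1 output), and 3
neutral marker genes used only for visualisation.  Genes map affinely to
network weights in ``[-1, 1]``.  The networks are tiny feed-forward maps
``z = O . [tanh(gain * I . x); 1]``; the appended unit signal is a bias neuron
not linked to the input layer.  Weights are set genetically; there is no
learning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

N_GENES = 34
_ANGLE = slice(0, 3)
_PRIMARY = slice(3, 21)     # 3x2 input weights + 3x4 output weights
_SECONDARY = slice(21, 31)  # 3x2 input weights + 1x4 output weights
_MARKER = slice(31, 34)


@dataclass
class Genome:
    """34 genes in [0, 1]; the 3 markers never affect the dynamics."""

    genes: np.ndarray

    def __post_init__(self) -> None:
        self.genes = np.asarray(self.genes, dtype=float)
        if self.genes.shape != (N_GENES,):
            raise ValueError(f"genome must have {N_GENES} genes")
        if np.any(self.genes < 0.0) or np.any(self.genes > 1.0):
            raise ValueError("genes must lie in [0, 1]")

    @property
    def markers(self) -> np.ndarray:
        """Neutral marker genes, usable as an RGB colour."""
        return self.genes[_MARKER]


@dataclass
class NeuralNet:
    """Three-layer net: input weights I, output weights O (last column bias)."""

    I: np.ndarray
    O: np.ndarray
    gain: float = 5.0

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return nn_eval(self, x)


def nn_eval(net: NeuralNet, x: np.ndarray) -> np.ndarray:
    """Evaluate a net on one input vector or a batch of column vectors.

    ``x`` of shape ``(n_in,)`` gives outputs of shape ``(n_out,)``; shape
    ``(n_in, m)`` gives ``(n_out, m)``.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[:, None]
    if x.shape[0] != net.I.shape[1]:
        raise ValueError(
            f"input length {x.shape[0]} does not match net ({net.I.shape[1]})"
        )
    y = net.I @ x
    yp = np.tanh(net.gain * y)
    yp = np.vstack([yp, np.ones((1, x.shape[1]))])
    z = net.O @ yp
    return z[:, 0] if single else z


def random_genome(rng: np.random.Generator) -> Genome:
    return Genome(rng.uniform(0.0, 1.0, N_GENES))


def decode_genome(genome: Genome) -> tuple[float, float, float, NeuralNet, NeuralNet]:
    """Decode a genome into branching angles and the two growth networks.

    Angle genes map affinely to ``theta1`` in [0, 90] deg, ``theta2`` in
    [-90, 0] deg and ``gamma`` in [0, 180] deg, so that the two child axes
    fork on opposite sides of the parent axis.  Weight genes map affinely
    from [0, 1] to [-1, 1].
    """
    g = genome.genes
    theta1 = 90.0 * g[0]
    theta2 = -90.0 * g[1]
    gamma = 180.0 * g[2]
    wp = 2.0 * g[_PRIMARY] - 1.0
    ws = 2.0 * g[_SECONDARY] - 1.0
    primary = NeuralNet(I=wp[:6].reshape(3, 2), O=wp[6:].reshape(3, 4))
    secondary = NeuralNet(I=ws[:6].reshape(3, 2), O=ws[6:].reshape(1, 4))
    return theta1, theta2, gamma, primary, secondary


def primary_policy(
    reserve: float, n_foliages: int, net: NeuralNet, V0: float
) -> tuple[float, float, float]:
    """Carbon-allocation policy for primary growth.

    Inputs are squashed to order 1: ``log10(1 + V_res/V0)/3`` and
    ``log10(1 + N_fol)/3``.  The raw outputs ``(z1, z2, z3)`` are mapped to the
    allocation simplex by a three-way softmax over ``(z1, z2, 0)`` — giving
    the proportion of reserve spent on new segments ``P_seg``, on seeds
    ``P_seed`` (so ``P_seg + P_seed <= 1`` holds by construction, the
    remainder staying in the reserve) — and to a photosensitivity
    ``p = (1 + tanh z3)/2`` in [0, 1].  A zero-weight genome is neutral:
    ``P_seg = P_seed = 1/3`` and ``p = 1/2``.
    """
    x = np.array([
        np.log10(1.0 + reserve / V0) / 3.0,
        np.log10(1.0 + n_foliages) / 3.0,
    ])
    z = nn_eval(net, x)
    zs = np.array([z[0], z[1], 0.0])
    zs -= zs.max()
    w = np.exp(zs)
    w /= w.sum()
    p = 0.5 * (1.0 + np.tanh(z[2]))
    return float(w[0]), float(w[1]), float(p)


S_MIN, S_MAX = 1.0, 6.0


def secondary_policy(
    sigma_rel: np.ndarray, n_fol_above: np.ndarray, net: NeuralNet
) -> np.ndarray:
    """Safety factor S in [1, 6] per segment (thigmomorphogenetic response).

    Inputs: felt relative stress ``sigma_max/sigma0`` clipped to [0, 2] and
    ``log10(1 + N_fol_above)/3``.  The raw output is squashed with a logistic
    map bracketing the midpoint 3.5 at zero weights.
    """
    sigma_rel = np.asarray(sigma_rel, dtype=float)
    n_fol_above = np.asarray(n_fol_above, dtype=float)
    if np.any(sigma_rel < 0):
        raise ValueError("sigma_rel must be >= 0")
    x = np.vstack([
        np.clip(sigma_rel, 0.0, 2.0),
        np.log10(1.0 + n_fol_above) / 3.0,
    ])
    z = nn_eval(net, x)[0]
    return S_MIN + (S_MAX - S_MIN) * 0.5 * (1.0 + np.tanh(z))


def mutate(genome: Genome, rng: np.random.Generator,
           p_mut: float = 0.05, delta_g: float = 0.005) -> Genome:
    """Return a mutated copy: each gene moves by ``eps*delta_g`` w.p. ``p_mut``.

    ``eps`` is standard normal; results are clamped to [0, 1].  Marker genes
    mutate like any other gene.
    """
    g = genome.genes.copy()
    hit = rng.uniform(size=N_GENES) < p_mut
    if np.any(hit):
        g[hit] += rng.standard_normal(int(hit.sum())) * delta_g
        np.clip(g, 0.0, 1.0, out=g)
    return Genome(g)


def save_genomes(path, genomes: list[Genome]) -> None:
    """One genome per line, 34 comma-separated floats in [0, 1]."""
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(",".join(repr(float(v)) for v in g.genes) + "\n")


def load_genomes(path) -> list[Genome]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            out.append(Genome(np.array([float(v) for v in line.split(",")])))
    return out
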