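"""JTT substitution model and pairwise maximum-likelihood distances.

The Jones-Taylor-Thornton (1992) empirical amino-acid model is realized as a
time-reversible rate matrix Q with Q_ab = S_ab * pi_b (a != b), scaled to one
expected substitution per site at stationarity.  Pairwise evolutionary
distances are obtained by maximizing, over the divergence time t, the
likelihood of the two aligned sequences under P(t) = exp(Qt), using only
columns where both sequences carry canonical residues ("pairwise deletion").

The estimator treats one sequence as drawn from the stationary distribution
and the other as its descendant; by time reversibility the pair ordering is
irrelevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

from .alignio import AlignedProteinSet, AMINO_ACIDS
from .errors import DistanceError, TEClassError

# ---------------------------------------------------------------------------
# Published JTT-1992 data (integer exchangeabilities, upper triangle in
# row-major order over A R N D C Q E G H I L K M F P S T W Y V, and the
# stationary amino-acid frequencies), as distributed with standard
# phylogenetics tools (PAML's jones.dat and equivalents).
# ---------------------------------------------------------------------------

_JTT_UPPER = np.array([
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378,
    475, 9, 11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44,
    5, 74, 101, 64, 126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12,
    263, 30, 10, 15, 503, 232, 8, 70, 16, 10, 49, 767, 130, 112, 11,
    7, 26, 15, 4, 15, 59, 38, 4, 46, 31, 9, 5, 59, 69, 17,
    23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26, 597, 9, 72,
    292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18,
    5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201,
    33, 55, 8, 47, 16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11,
    229, 21, 479, 89, 10, 40, 245, 9, 32, 961, 14, 388, 248, 102, 59,
    25, 52, 24, 180, 65, 4, 21, 47, 103, 10, 8, 14, 43, 16, 29,
    226, 24, 18, 323, 17, 92, 12, 53, 536, 62, 285, 118, 6, 10, 23,
    477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
], dtype=float)

_JTT_FREQS = np.array([
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803, 0.040752, 0.061830,
    0.073152, 0.022944, 0.053761, 0.091904, 0.058676, 0.023826, 0.040126,
    0.050901, 0.068765, 0.058565, 0.014261, 0.032102, 0.066005,
])


def _jtt_exchangeabilities() -> np.ndarray:
    S = np.zeros((20, 20))
    iu = np.triu_indices(20, 1)
    S[iu] = _JTT_UPPER
    return S + S.T


@dataclass
class SubstitutionModel:
    """A time-reversible empirical amino-acid substitution model.

    Attributes
    ----------
    S : (20, 20) symmetric nonnegative exchangeability matrix.
    pi : stationary amino-acid frequencies (sum to 1, all positive).
    Q : generator with Q_ab = S_ab * pi_b off-diagonal, zero row sums,
        scaled so that -sum_a pi_a Q_aa == 1 substitution per site.
    """

    S: np.ndarray
    pi: np.ndarray
    name: str = "custom"
    Q: np.ndarray = field(init=False)
    _eigvals: np.ndarray = field(init=False, repr=False)
    _left: np.ndarray = field(init=False, repr=False)
    _right: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        S = np.asarray(self.S, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        if S.shape != (20, 20) or not np.allclose(S, S.T):
            raise TEClassError("exchangeability matrix must be symmetric 20x20")
        if np.any(pi <= 0):
            raise TEClassError("all equilibrium frequencies must be positive")
        pi = pi / pi.sum()
        Q = S * pi[None, :]
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        rate = -np.dot(pi, np.diag(Q))
        Q /= rate
        self.S, self.pi, self.Q = S, pi, Q
        # Eigendecomposition of the symmetrized generator
        # B = diag(sqrt(pi)) Q diag(1/sqrt(pi)); P(t) recovered from it.
        sqrt_pi = np.sqrt(pi)
        B = (sqrt_pi[:, None] * Q) / sqrt_pi[None, :]
        w, V = np.linalg.eigh((B + B.T) / 2.0)
        self._eigvals = w
        self._right = V / sqrt_pi[:, None] * 1.0  # diag(1/sqrt(pi)) V
        self._left = (V * sqrt_pi[:, None]).T     # V^T diag(sqrt(pi))

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, entries clamped at 0.

        Raises for negative t.
        """
        if t < 0:
            raise TEClassError(f"branch length must be >= 0, got {t}")
        P = (self._right * np.exp(self._eigvals * t)) @ self._left
        np.clip(P, 0.0, None, out=P)
        return P


def jtt_model() -> SubstitutionModel:
    """The JTT-1992 model with its published frequencies."""
    return SubstitutionModel(_jtt_exchangeabilities(), _JTT_FREQS, name="JTT")


#: Module-level default model instance (eigendecomposition cached).
JTT = jtt_model()


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    return model.transition_matrix(t)


# ---------------------------------------------------------------------------
# Pairwise ML distance
# ---------------------------------------------------------------------------

#: Upper bound on estimated distances (substitutions/site); estimates at the
#: bound are flagged as saturated.
MAX_DISTANCE = 10.0
MIN_DISTANCE = 1e-6
LOW_COVERAGE_SITES = 20

FLAG_OK = "ok"
FLAG_SATURATED = "saturated"
FLAG_LOW_COVERAGE = "low_coverage"


def _pair_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """20x20 matrix of aligned residue-pair counts over shared sites."""
    mask = (a >= 0) & (b >= 0)
    if not mask.any():
        return np.zeros((20, 20))
    flat = np.bincount(a[mask].astype(np.int64) * 20 + b[mask], minlength=400)
    return flat.reshape(20, 20).astype(float)


def _loglik_from_counts(counts: np.ndarray, model: SubstitutionModel):
    """Return f(t) = log L(t) for the pair-count sufficient statistic."""
    rows, cols = np.nonzero(counts)
    c = counts[rows, cols]
    log_pi = np.log(model.pi[rows])
    right = model._right[rows]   # (m, 20)
    left = model._left[:, cols]  # (20, m)

    def loglik(t: float) -> float:
        p = np.einsum("mk,km->m", right * np.exp(model._eigvals * t), left)
        p = np.maximum(p, 1e-300)
        return float(np.dot(c, log_pi + np.log(p)))

    return loglik


def pairwise_ml_distance(
    seq_a: np.ndarray | str,
    seq_b: np.ndarray | str,
    model: SubstitutionModel = JTT,
) -> tuple[float, int, str]:
    """ML evolutionary distance between two aligned rows.

    Accepts integer-encoded rows (gaps/ambiguity as -1) or raw aligned
    strings.  Only shared sites — columns where both rows are canonical —
    enter the likelihood.  Returns ``(distance, shared_sites, flag)``.

    Raises :class:`DistanceError` when the pair shares no sites.
    """
    a = _encode_row(seq_a)
    b = _encode_row(seq_b)
    if a.shape != b.shape:
        raise DistanceError("aligned rows must have equal length")
    counts = _pair_counts(a, b)
    n_shared = int(counts.sum())
    if n_shared == 0:
        raise DistanceError("no shared (pairwise-complete) sites for pair")
    # time reversibility makes (a, b) and (b, a) site patterns equivalent;
    # symmetrizing the counts makes the estimate exactly swap-invariant
    loglik = _loglik_from_counts(counts + counts.T, model)
    # Identical sequences: the likelihood is maximized at t -> 0.
    if np.trace(counts) == n_shared:
        d = MIN_DISTANCE
    else:
        res = minimize_scalar(
            lambda t: -loglik(t),
            bounds=(MIN_DISTANCE, MAX_DISTANCE),
            method="bounded",
            options={"xatol": 1e-8},
        )
        d = float(res.x)
    flag = FLAG_OK
    if d >= MAX_DISTANCE - 1e-3:
        d = MAX_DISTANCE
        flag = FLAG_SATURATED
    elif n_shared < LOW_COVERAGE_SITES:
        flag = FLAG_LOW_COVERAGE
    return d, n_shared, flag


def _encode_row(seq) -> np.ndarray:
    if isinstance(seq, str):
        idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        return np.array([idx.get(ch, -1) for ch in seq.upper()], dtype=np.int8)
    return np.asarray(seq)


@dataclass
class EvolutionaryDistanceMatrix:
    """Symmetric j x j matrix of pairwise ML distances.

    Carries per-pair shared-site counts and quality flags alongside the
    distances themselves.
    """

    ids: list[str]
    d: np.ndarray
    shared_sites: np.ndarray
    flags: dict[tuple[str, str], str]

    def __post_init__(self) -> None:
        j = len(self.ids)
        if self.d.shape != (j, j):
            raise TEClassError("distance matrix shape does not match ids")

    @property
    def size(self) -> int:
        return len(self.ids)

    def index(self, seq_id: str) -> int:
        return self.ids.index(seq_id)

    def submatrix(self, ids: list[str]) -> "EvolutionaryDistanceMatrix":
        idx = [self.index(i) for i in ids]
        sub = self.d[np.ix_(idx, idx)]
        shared = self.shared_sites[np.ix_(idx, idx)]
        flags = {
            (a, b): f
            for (a, b), f in self.flags.items()
            if a in set(ids) and b in set(ids)
        }
        return EvolutionaryDistanceMatrix(list(ids), sub, shared, flags)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t")

    def to_phylip(self, path: str | Path) -> None:
        """Write a PHYLIP-style square distance matrix."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sid in enumerate(self.ids):
                row = " ".join(f"{x:.8f}" for x in self.d[i])
                fh.write(f"{sid}  {row}\n")


def distance_matrix(
    aln: AlignedProteinSet, model: SubstitutionModel = JTT
) -> EvolutionaryDistanceMatrix:
    """All-pairs JTT ML distances under pairwise deletion.

    Raises :class:`DistanceError` naming the first pair with zero shared
    sites.
    """
    if len(aln) < 2:
        raise DistanceError("need at least 2 sequences for a distance matrix")
    enc = aln.encoded()
    j = len(aln)
    d = np.zeros((j, j))
    shared = np.zeros((j, j), dtype=int)
    np.fill_diagonal(shared, (enc >= 0).sum(axis=1))
    flags: dict[tuple[str, str], str] = {}
    ids = aln.ids
    for x in range(j):
        for y in range(x + 1, j):
            try:
                dist, n_sh, flag = pairwise_ml_distance(enc[x], enc[y], model)
            except DistanceError as exc:
                raise DistanceError(
                    f"pair ({ids[x]!r}, {ids[y]!r}): {exc}"
                ) from exc
            d[x, y] = d[y, x] = dist
            shared[x, y] = shared[y, x] = n_sh
            flags[(ids[x], ids[y])] = flag
    return EvolutionaryDistanceMatrix(ids, d, shared, flags)
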