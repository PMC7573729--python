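"""Time-reversible substitution models with gamma + invariant-sites rate mixtures.

Supported model kinds:

``JC69``
    Equal-frequency, equal-exchangeability nucleotide model; its distance has
    the closed form -(3/4) ln(1 - (4/3) p), which several tests use as an
    oracle.
``GTR``
    General time-reversible nucleotide model.  Exchangeabilities and base
    frequencies are configuration inputs (model selection is upstream of this
    package); the defaults are all-equal exchangeabilities with empirical or
    uniform frequencies.
``JTT``
    The Jones-Taylor-Thornton (1992) empirical amino-acid model, embedded as
    the standard published integer exchangeability table and frequency vector.

Rate heterogeneity follows the discrete-gamma convention: K equal-probability
categories whose rates are the within-bin means of a Gamma(alpha, alpha)
density, normalized to mean 1, combined with a proportion ``p_inv`` of
invariant sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .alignment import AMINO_ACIDS, NUCLEOTIDES
from .errors import DupdivError

# Lower triangle (row-wise: R|A, N|A R, D|A R N, ...) of the published JTT
# exchangeability table, followed by the JTT equilibrium frequencies, in
# amino-acid order ARNDCQEGHILKMFPSTWYV.
_JTT_LOWER = [
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30, 35, 54, 15, 194, 378, 475, 9,
    11, 298, 45, 16, 113, 310, 29, 137, 328, 22, 38, 646, 44, 5, 74, 101, 64,
    126, 20, 17, 528, 34, 86, 58, 81, 391, 47, 12, 263, 30, 10, 15, 503, 232,
    8, 70, 16, 10, 49, 767, 130, 112, 11, 7, 26, 15, 4, 15, 59, 38, 4, 46,
    31, 9, 5, 59, 69, 17, 23, 7, 31, 78, 14, 223, 42, 115, 209, 62, 323, 26,
    597, 9, 72, 292, 43, 4, 164, 53, 51, 18, 24, 20, 119, 26, 12, 9, 181, 18,
    5, 18, 30, 32, 10, 7, 45, 23, 6, 6, 27, 14, 5, 24, 201, 33, 55, 8, 47,
    16, 56, 45, 33, 40, 115, 73, 46, 8, 573, 11, 229, 21, 479, 89, 10, 40,
    245, 9, 32, 961, 14, 388, 248, 102, 59, 25, 52, 24, 180, 65, 4, 21, 47,
    103, 10, 8, 14, 43, 16, 29, 226, 24, 18, 323, 17, 92, 12, 53, 536, 62,
    285, 118, 6, 10, 23, 477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
]
_JTT_FREQS = [
    0.076748, 0.051691, 0.042645, 0.051544, 0.019803, 0.040752, 0.061830,
    0.073152, 0.022944, 0.053761, 0.091904, 0.058676, 0.023826, 0.040126,
    0.050901, 0.068765, 0.058565, 0.014261, 0.032102, 0.066005,
]


def _lower_to_symmetric(lower, n):
    m = np.zeros((n, n))
    it = iter(lower)
    for i in range(1, n):
        for j in range(i):
            m[i, j] = m[j, i] = next(it)
    return m


def jtt_exchangeabilities() -> np.ndarray:
    return _lower_to_symmetric(_JTT_LOWER, 20)


def jtt_frequencies() -> np.ndarray:
    f = np.asarray(_JTT_FREQS)
    return f / f.sum()


@dataclass(frozen=True)
class RateMixture:
    """Discrete-gamma category rates plus an invariant-site proportion."""

    rates: tuple[float, ...] = (1.0,)
    p_inv: float = 0.0

    def __post_init__(self):
        r = np.asarray(self.rates)
        if np.any(r < 0) or abs(r.mean() - 1.0) > 1e-9:
            raise DupdivError("category rates must be >= 0 with mean 1")
        if not (0.0 <= self.p_inv < 1.0):
            raise DupdivError("p_inv must lie in [0, 1)")

    @classmethod
    def discrete_gamma(cls, alpha: float, k: int = 4, p_inv: float = 0.0):
        """Equal-probability discrete gamma: category rate = bin mean."""
        if alpha <= 0 or k < 1:
            raise DupdivError("alpha must be > 0 and K >= 1")
        if k == 1:
            return cls((1.0,), p_inv)
        edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=alpha, scale=1.0 / alpha)
        upper = gammainc(alpha + 1.0, alpha * edges[1:])
        lower = gammainc(alpha + 1.0, alpha * edges[:-1])
        rates = k * (upper - lower)
        rates = rates / rates.mean()  # remove residual float error
        return cls(tuple(rates), p_inv)


@dataclass(frozen=True)
class SubstitutionModel:
    """A reversible rate matrix Q = S * diag(pi), normalized to rate 1.

    ``exchangeabilities`` is the symmetric positive-off-diagonal matrix S;
    ``freqs`` the equilibrium distribution pi.  Q is scaled so the expected
    substitution rate at equilibrium is 1, i.e. -sum_i pi_i Q_ii = 1, making
    branch lengths expected substitutions per site.
    """

    kind: str
    states: str
    freqs: tuple[float, ...]
    exchangeabilities: tuple[tuple[float, ...], ...]

    @classmethod
    def jc69(cls) -> "SubstitutionModel":
        s = np.ones((4, 4)) - np.eye(4)
        return cls("JC69", NUCLEOTIDES, tuple(np.full(4, 0.25)), _t(s))

    @classmethod
    def gtr(cls, freqs=None, exchangeabilities=None) -> "SubstitutionModel":
        f = np.full(4, 0.25) if freqs is None else np.asarray(freqs, dtype=float)
        if f.shape != (4,) or np.any(f <= 0):
            raise DupdivError("GTR frequencies must be 4 positive values")
        f = f / f.sum()
        if exchangeabilities is None:
            s = np.ones((4, 4)) - np.eye(4)
        else:
            s = np.asarray(exchangeabilities, dtype=float)
            if s.shape != (4, 4) or not np.allclose(s, s.T):
                raise DupdivError("GTR exchangeabilities must be symmetric 4x4")
        return cls("GTR", NUCLEOTIDES, tuple(f), _t(s))

    @classmethod
    def jtt(cls) -> "SubstitutionModel":
        return cls(
            "JTT", AMINO_ACIDS, tuple(jtt_frequencies()), _t(jtt_exchangeabilities())
        )

    @classmethod
    def hky(cls, kappa: float, freqs=None) -> "SubstitutionModel":
        """HKY85 as a GTR special case: transitions weighted by kappa."""
        s = np.ones((4, 4)) - np.eye(4)
        # state order ACGT: transitions are A<->G (0,2) and C<->T (1,3)
        s[0, 2] = s[2, 0] = kappa
        s[1, 3] = s[3, 1] = kappa
        return cls.gtr(freqs=freqs, exchangeabilities=s).replace_kind("HKY")

    def replace_kind(self, kind: str) -> "SubstitutionModel":
        return SubstitutionModel(kind, self.states, self.freqs, self.exchangeabilities)

    # ------------------------------------------------------------------
    @cached_property
    def pi(self) -> np.ndarray:
        return np.asarray(self.freqs)

    @cached_property
    def Q(self) -> np.ndarray:
        s = np.asarray(self.exchangeabilities)
        q = s * self.pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -np.sum(self.pi * np.diag(q))
        return q / scale

    @cached_property
    def _eigen(self):
        # reversible Q: symmetrize with pi^(1/2) and use a symmetric eigensolver
        rp = np.sqrt(self.pi)
        b = (rp[:, None] * self.Q) / rp[None, :]
        w, u = np.linalg.eigh(0.5 * (b + b.T))
        left = u.T * rp[None, :]          # rows: u^T diag(sqrt(pi))
        right = u / rp[:, None]           # diag(1/sqrt(pi)) u
        return w, right, left

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); rows sum to 1, P(0) = I."""
        if not np.isfinite(t) or t < 0:
            raise DupdivError(f"branch length must be finite and >= 0, got {t}")
        w, right, left = self._eigen
        p = (right * np.exp(w * t)[None, :]) @ left
        p = np.clip(p, 0.0, None)
        return p / p.sum(axis=1, keepdims=True)

    def state_index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.states)}


def _t(m: np.ndarray):
    return tuple(tuple(float(x) for x in row) for row in m)


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    return model.transition_matrix(t)
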