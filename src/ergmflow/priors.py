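"""Gaussian priors / proposal distributions over ERGM parameter vectors."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class PriorError(ValueError):
    pass


def _default_mean() -> np.ndarray:
    return np.zeros(3)


def _default_cov() -> np.ndarray:
    return 10.0 * np.eye(3)


@dataclass(frozen=True)
class PriorSpec:
    """Multivariate normal prior ``theta ~ N(mean, covariance)``.

    The default ``N(0, 10 I)`` is the wide prior used for amortised posterior
    estimation and for the exchange-algorithm reference fits.
    """

    mean: np.ndarray = field(default_factory=_default_mean)
    covariance: np.ndarray = field(default_factory=_default_cov)

    def __post_init__(self) -> None:
        m = np.atleast_1d(np.asarray(self.mean, dtype=float))
        c = np.atleast_2d(np.asarray(self.covariance, dtype=float))
        if c.shape != (m.size, m.size):
            raise PriorError(f"covariance shape {c.shape} does not match mean dim {m.size}")
        try:
            np.linalg.cholesky(c)
        except np.linalg.LinAlgError as exc:
            raise PriorError("covariance is not symmetric positive definite") from exc
        object.__setattr__(self, "mean", m)
        object.__setattr__(self, "covariance", c)

    @property
    def dim(self) -> int:
        return self.mean.size

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.multivariate_normal(self.mean, self.covariance, size=int(n))

    def log_pdf(self, theta: np.ndarray) -> np.ndarray:
        return np.atleast_1d(
            stats.multivariate_normal.logpdf(
                np.atleast_2d(theta), mean=self.mean, cov=self.covariance
            )
        )

    def log_pdf_quantile(self, q: float) -> float:
        """Exact quantile of ``log pi(theta)`` when ``theta ~ pi``.

        For a Gaussian, ``log pi(theta) = const - r^2 / 2`` with ``r^2``
        chi-squared(dim), so low log-density quantiles map to upper chi2
        quantiles — used by the leakage diagnostic.
        """
        const = float(self.log_pdf(self.mean)[0])
        return const - 0.5 * float(stats.chi2.ppf(1.0 - q, df=self.dim))
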