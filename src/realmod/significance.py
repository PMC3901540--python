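"""Null-ensemble summaries: means, percentile CIs, deltas and quadrants.

The empirical Q and Q'_R of a network are compared with their distribution
over null replicates. The "90% confidence interval" is realized as the
percentile interval (5th–95th percentile at the default level); deltas are
the empirical value minus the retained-replicate mean, so dQ < 0 reads "less
modular than expected by chance". A statistic is flagged when the empirical
value falls strictly outside its interval, and the joint outcome is labelled
by quadrant — the interesting conflicted case being a network whose Q is
lower than chance while its realized modularity Q'_R is higher (its modules,
however weak by Q, are still internally denser than the null's).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import GraphError
from .null_model import NullEnsemble

__all__ = [
    "NullTestReport",
    "summarize",
    "classify",
    "QUADRANTS",
]

QUADRANTS = (
    "more-modular-both",
    "less-modular-both",
    "conflicted-Q-low-QR-high",
    "conflicted-Q-high-QR-low",
    "indistinct",
)


@dataclass(frozen=True)
class NullTestReport:
    """Empirical vs null comparison for one network."""

    q: float
    q_prime: float
    null_mean_q: float
    null_var_q: float
    null_mean_q_prime: float
    null_var_q_prime: float
    ci_q: tuple
    ci_q_prime: tuple
    delta_q: float
    delta_q_prime: float
    q_outside: bool
    q_prime_outside: bool
    level: float
    retained: int
    discarded: int
    quadrant: str

    def to_record(self) -> dict:
        """Flat record in the conventional column naming (q, qr, qe, eqe, ...)."""
        return {
            "q": self.q,
            "qr": self.q_prime,
            "qe": self.null_mean_q,
            "eqe": self.null_var_q,
            "qre": self.null_mean_q_prime,
            "eqre": self.null_var_q_prime,
            "q_ci_low": self.ci_q[0],
            "q_ci_high": self.ci_q[1],
            "qr_ci_low": self.ci_q_prime[0],
            "qr_ci_high": self.ci_q_prime[1],
            "dq": self.delta_q,
            "dqr": self.delta_q_prime,
            "q_outside_ci": self.q_outside,
            "qr_outside_ci": self.q_prime_outside,
            "quadrant": self.quadrant,
            "level": self.level,
            "retained": self.retained,
            "discarded": self.discarded,
        }


def _quadrant(dq: float, dqr: float, q_out: bool, qr_out: bool) -> str:
    # the four named quadrants require both statistics to fall outside their
    # intervals; a single-signal outcome is reported as indistinct
    if not (q_out and qr_out):
        return "indistinct"
    if dq > 0 and dqr > 0:
        return "more-modular-both"
    if dq < 0 and dqr < 0:
        return "less-modular-both"
    if dq < 0 and dqr > 0:
        return "conflicted-Q-low-QR-high"
    return "conflicted-Q-high-QR-low"


def summarize(
    ensemble: NullEnsemble,
    empirical_q: float,
    empirical_q_prime: float,
    level: float = 0.90,
) -> NullTestReport:
    """Summarize a null ensemble against the empirical statistics.

    Means and (sample) variances are taken over the retained replicates;
    the CI is the percentile interval at quantiles (1-level)/2 and
    1-(1-level)/2 with linear interpolation.
    """
    if ensemble.retained < 2:
        raise GraphError("need at least 2 retained replicates to summarize")
    if not 0.0 < level < 1.0:
        raise GraphError(f"CI level must be in (0, 1), got {level!r}")
    qs = np.asarray(ensemble.q_values, dtype=float)
    qrs = np.asarray(ensemble.q_prime_values, dtype=float)
    alpha = (1.0 - level) / 2.0
    ci_q = tuple(float(x) for x in np.quantile(qs, [alpha, 1.0 - alpha]))
    ci_qr = tuple(float(x) for x in np.quantile(qrs, [alpha, 1.0 - alpha]))
    mean_q = float(qs.mean())
    mean_qr = float(qrs.mean())
    dq = empirical_q - mean_q
    dqr = empirical_q_prime - mean_qr
    q_out = empirical_q < ci_q[0] or empirical_q > ci_q[1]
    qr_out = empirical_q_prime < ci_qr[0] or empirical_q_prime > ci_qr[1]
    return NullTestReport(
        q=empirical_q,
        q_prime=empirical_q_prime,
        null_mean_q=mean_q,
        null_var_q=float(qs.var(ddof=1)),
        null_mean_q_prime=mean_qr,
        null_var_q_prime=float(qrs.var(ddof=1)),
        ci_q=ci_q,
        ci_q_prime=ci_qr,
        delta_q=dq,
        delta_q_prime=dqr,
        q_outside=q_out,
        q_prime_outside=qr_out,
        level=level,
        retained=ensemble.retained,
        discarded=ensemble.discarded,
        quadrant=_quadrant(dq, dqr, q_out, qr_out),
    )


def classify(report: NullTestReport) -> str:
    """Quadrant label of a report (recomputed from its fields)."""
    return _quadrant(report.delta_q, report.delta_q_prime, report.q_outside, report.q_prime_outside)
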