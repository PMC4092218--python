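"""Deregression of EBVs and residual information weights.

An EBV is a shrunken blend of an animal's own information, its descendants'
and its parents'.  Regressing SNP effects directly on EBVs therefore
double-counts family information and picks up markers that track
relatedness rather than trait loci.  Deregression inverts the shrinkage and
strips the parent-average contribution, leaving a pseudo-phenotype (dEBV)
carrying only own + descendant information, together with a reliability
r2* for that pseudo-phenotype and a residual weight w used as a diagonal
weight matrix in the genomic regression.

The algebra works on the 2x2 mixed-model system for the (parent-average,
individual) pair.  With lambda = (1 - h2) / h2:

    alpha   = 1 / (0.5 - r2_PA)
    delta   = (0.5 - r2_PA) / (1 - r2_i)
    Z'Z_PA  = lambda * (0.5 * alpha - 4) + 0.5 * lambda * sqrt(alpha^2 + 16 / delta)
    Z'Z_i   = delta * Z'Z_PA + 2 * lambda * (2 * delta - 1)

    C = [[Z'Z_PA + 4 lambda, -2 lambda],
         [-2 lambda,          Z'Z_i + 2 lambda]]

    (y_PA, y_i) = C @ (pa_ebv, ebv)
    dEBV        = y_i / Z'Z_i
    r2*         = 1 - lambda / (Z'Z_i + lambda)

and the residual weight, with c the fraction of genetic variance the
markers do not capture:

    w = (1 - h2) / [ (c + (1 - r2*) / r2*) * h2 ]
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DeregressionDetail",
    "deregress_ebv",
    "compute_weight",
    "deregress_cohort",
]


class DomainError(ValueError):
    """Input outside the domain of the deregression algebra."""


@dataclass
class DeregressionDetail:
    """Intermediate quantities of the 2x2 deregression system.

    Exposed so the round-trip identity (re-applying the coefficient matrix
    to the solved effects reproduces the EBV pair) can be verified.
    """

    lam: float
    alpha: float
    delta: float
    zpz_pa: float
    zpz_i: float
    rhs_pa: float
    rhs_i: float
    debv: float
    reliability_debv: float

    @property
    def coefficient_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.zpz_pa + 4.0 * self.lam, -2.0 * self.lam],
                [-2.0 * self.lam, self.zpz_i + 2.0 * self.lam],
            ]
        )


def deregress_ebv(
    ebv: float,
    pa_ebv: float,
    reliability_i: float,
    reliability_pa: float,
    h2: float,
    return_detail: bool = False,
) -> tuple[float, float] | DeregressionDetail:
    """Deregress one animal's EBV, removing the parent-average contribution.

    Parameters
    ----------
    ebv, pa_ebv : the animal's EBV and its parent-average EBV (trait units).
    reliability_i, reliability_pa : r2 of the EBV and of the parent average;
        r2_PA must be strictly below 0.5 and r2_i strictly below 1.
    h2 : trait heritability in (0, 1).
    return_detail : also return the intermediate 2x2-system quantities.

    Returns
    -------
    ``(debv, reliability_debv)``, or a :class:`DeregressionDetail` when
    ``return_detail`` is set.
    """
    if not 0.0 < h2 < 1.0:
        raise DomainError(f"h2 must be in (0, 1), got {h2}")
    if not 0.0 <= reliability_pa < 0.5:
        raise DomainError(
            f"parent-average reliability must be in [0, 0.5), got {reliability_pa}"
        )
    if not 0.0 <= reliability_i < 1.0:
        raise DomainError(f"reliability must be in [0, 1), got {reliability_i}")

    lam = (1.0 - h2) / h2
    alpha = 1.0 / (0.5 - reliability_pa)
    delta = (0.5 - reliability_pa) / (1.0 - reliability_i)
    zpz_pa = lam * (0.5 * alpha - 4.0) + 0.5 * lam * np.sqrt(alpha**2 + 16.0 / delta)
    zpz_i = delta * zpz_pa + 2.0 * lam * (2.0 * delta - 1.0)
    if zpz_i <= 0.0:
        raise DomainError(
            "individual information content non-positive: the EBV carries "
            f"less information (r2_i={reliability_i}) than its parent average "
            f"(r2_PA={reliability_pa}) supplies"
        )

    rhs_pa = (zpz_pa + 4.0 * lam) * pa_ebv - 2.0 * lam * ebv
    rhs_i = -2.0 * lam * pa_ebv + (zpz_i + 2.0 * lam) * ebv
    debv = rhs_i / zpz_i
    rel = 1.0 - lam / (zpz_i + lam)

    if return_detail:
        return DeregressionDetail(
            lam=lam,
            alpha=alpha,
            delta=delta,
            zpz_pa=zpz_pa,
            zpz_i=zpz_i,
            rhs_pa=rhs_pa,
            rhs_i=rhs_i,
            debv=float(debv),
            reliability_debv=float(rel),
        )
    return float(debv), float(rel)


def compute_weight(reliability_debv: float, h2: float, c: float = 0.5) -> float:
    """Residual weight for one deregressed record.

    ``c`` is the fraction of genetic variance not captured by the markers.
    The weight grows monotonically with the dEBV reliability: animals whose
    dEBV is backed by many progeny records get w > 1, animals with only an
    own record fall below 1.
    """
    r2 = reliability_debv
    if not 0.0 < r2 < 1.0:
        raise DomainError(f"reliability_debv must be in (0, 1), got {r2}")
    if not 0.0 <= c <= 1.0:
        raise DomainError(f"c must be in [0, 1], got {c}")
    if not 0.0 < h2 < 1.0:
        raise DomainError(f"h2 must be in (0, 1), got {h2}")
    return (1.0 - h2) / ((c + (1.0 - r2) / r2) * h2)


def deregress_cohort(
    ebv_table: pd.DataFrame,
    h2: float,
    c: float = 0.5,
    drop_invalid: bool = True,
) -> pd.DataFrame:
    """Deregress a whole EBV table.

    Expects columns ``animal_id, ebv, reliability_i, pa_ebv,
    reliability_pa``; returns ``animal_id, debv, reliability_debv, weight``.
    Animals whose record is outside the algebra's domain (r2_PA >= 0.5,
    r2_i at the boundary, or non-positive individual information) are
    dropped with ``drop_invalid`` (the default) or raise otherwise.
    """
    out = []
    for row in ebv_table.itertuples(index=False):
        try:
            debv, rel = deregress_ebv(
                ebv=row.ebv,
                pa_ebv=row.pa_ebv,
                reliability_i=row.reliability_i,
                reliability_pa=row.reliability_pa,
                h2=h2,
            )
            weight = compute_weight(rel, h2=h2, c=c)
        except DomainError:
            if drop_invalid:
                continue
            raise
        out.append((row.animal_id, debv, rel, weight))
    return pd.DataFrame(
        out, columns=["animal_id", "debv", "reliability_debv", "weight"]
    )
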