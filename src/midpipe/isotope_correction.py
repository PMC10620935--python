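"""Natural ¹³C abundance correction for isotopologue intensities.

On a high-resolution instrument the isotopic contributions of non-carbon
elements are mass-resolved away from the carbon isotopologue envelope, so
only the tracer element (carbon) needs correcting.  For a metabolite with
n carbons of which j carry tracer label, each of the remaining n−j
carbons is independently ¹³C with natural probability p, so the observed
mass-shift distribution given j true labels is binomial:

    M[i, j] = C(n−j, i−j) · p^(i−j) · (1−p)^(n−i)   for i ≥ j, else 0.

M is lower-triangular and column-stochastic.  Measured vectors x are
de-convolved by solving M·y = x, by non-negative least squares (default;
noisy data would otherwise yield negative isotopologues) or by direct
triangular inversion with negatives clipped (kept for oracle tests).

An optional tracer-purity term models tracer atoms that are not actually
labeled: with purity u, j nominal labels yield Binomial(j, u) effective
labels, and the kernel becomes the composition of the natural-abundance
matrix with that dilution (the matrix is then no longer triangular).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from scipy.stats import binom

from .data_model import IsotopologueTable, MoleculeSpec

logger = logging.getLogger(__name__)

#: Natural terrestrial abundance of ¹³C.
NATURAL_13C = 0.0107


@dataclass(frozen=True)
class CorrectionConfig:
    """Parameters of the natural-abundance correction.

    p_nat
        Probability that an unlabeled carbon is ¹³C (default: the
        standard terrestrial abundance 0.0107).
    tracer_purity
        Fraction of tracer atoms actually labeled; 1.0 disables the
        purity term.
    solver
        ``nnls`` (non-negative least squares, default) or ``direct``
        (triangular solve with negatives clipped to zero).
    """

    p_nat: float = NATURAL_13C
    tracer_purity: float = 1.0
    solver: str = "nnls"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_nat < 0.5:
            raise ValueError(f"p_nat must be in [0, 0.5), got {self.p_nat}")
        if not 0.0 < self.tracer_purity <= 1.0:
            raise ValueError(f"tracer_purity must be in (0, 1], got {self.tracer_purity}")
        if self.solver not in ("nnls", "direct"):
            raise ValueError(f"solver must be 'nnls' or 'direct', got {self.solver!r}")


def build_correction_matrix(n: int, cfg: CorrectionConfig = CorrectionConfig()) -> np.ndarray:
    """The (n+1)×(n+1) kernel mapping true label counts to observed mass shifts.

    Column j is the distribution of observed shifts given j tracer-labeled
    carbons; columns sum to 1.  With tracer_purity < 1 the natural-abundance
    matrix is pre-composed with the binomial label-dilution matrix.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    j = np.arange(n + 1)
    i = j[:, None]
    # Binomial natural labeling of the n-j unlabeled carbons.
    M = binom.pmf(i - j[None, :], n - j[None, :], cfg.p_nat)
    M = np.where(i >= j[None, :], M, 0.0)
    if cfg.tracer_purity < 1.0:
        # D[i, j]: j nominal labels -> i effective labels, each kept w.p. u.
        D = binom.pmf(i, j[None, :], cfg.tracer_purity)
        M = M @ D
    return M


def correct_vector(x: np.ndarray, M: np.ndarray, solver: str = "nnls") -> np.ndarray:
    """Solve M·y = x for the tracer-label distribution y ≥ 0."""
    if solver == "nnls":
        y, _ = scipy.optimize.nnls(M, x)
    else:
        y = scipy.linalg.solve_triangular(M, x, lower=True)
        np.clip(y, 0.0, None, out=y)
    return y


def correct_natural_abundance(
    thresholded: IsotopologueTable,
    molecules: dict[str, MoleculeSpec],
    cfg: CorrectionConfig = CorrectionConfig(),
) -> IsotopologueTable:
    """De-convolve natural ¹³C contributions from every metabolite-sample vector.

    Vectors containing any missing entry produce an all-missing corrected
    vector (the solve needs the complete envelope).  Corrected intensities
    are *not* renormalized to the observed total; the per-vector total
    signal change is logged in aggregate.
    """
    values = thresholded.values.copy()
    total_in = 0.0
    total_out = 0.0
    for met in thresholded.metabolites:
        n = molecules[met].n_carbons
        rows = values.index[values.index.get_level_values("metabolite") == met]
        shifts = rows.get_level_values("shift")
        if len(rows) != n + 1 or set(shifts) != set(range(n + 1)):
            raise ValueError(f"{met}: incomplete shift vector (need m+0..m+{n})")
        M = build_correction_matrix(n, cfg)
        order = rows[np.argsort(shifts)]
        block = values.loc[order].to_numpy(dtype=float)
        out = np.full_like(block, np.nan)
        for col in range(block.shape[1]):
            x = block[:, col]
            if np.isnan(x).any():
                continue
            y = correct_vector(x, M, cfg.solver)
            out[:, col] = y
            total_in += x.sum()
            total_out += y.sum()
        values.loc[order] = out
    if total_in > 0:
        logger.info(
            "natural-abundance correction: total signal %.6g -> %.6g (%.2f%%)",
            total_in,
            total_out,
            100.0 * total_out / total_in,
        )
    return thresholded.advance(values, "corrected")


def write_correction_matrix(n: int, cfg: CorrectionConfig, path) -> None:
    """Audit dump of one metabolite's correction matrix."""
    M = build_correction_matrix(n, cfg)
    df = pd.DataFrame(
        M,
        index=[f"observed_m{i}" for i in range(n + 1)],
        columns=[f"true_m{j}" for j in range(n + 1)],
    )
    df.to_csv(path, sep="\t")
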