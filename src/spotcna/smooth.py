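"""Per-chromosome pyramidal moving-average smoothing and intensity rescaling.

Each gene's centred log expression is replaced by a weighted average over a
window of its nearest genes on the same chromosome, with weights decaying
linearly from the window centre (a pyramid). Two centring steps and an
inverse-log transform then turn smoothed log expression into relative
expression intensities where copy-neutral ~= 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

from .types import GenePositions, IntensityMatrix, ValidationError

log = logging.getLogger(__name__)


@dataclass
class SmoothingConfig:
    """window_k: full window width (odd, default 101); a chromosome with
    fewer genes uses its own length instead."""

    window_k: int = 101

    def __post_init__(self) -> None:
        if self.window_k < 3 or self.window_k % 2 == 0:
            raise ValidationError("window_k must be odd and >= 3")


def half_window(n_genes: int, window_k: int) -> int:
    """m = (k - 1) / 2 with k shrunk to the chromosome length when shorter."""
    k = min(window_k, n_genes)
    return max((k - 1) // 2, 0)


def pyramid_weights(i: int, n: int, m: int) -> np.ndarray:
    """Normalized pyramid weights for gene ``i`` (1-based) of ``n`` on a chromosome.

    The window spans genes max(1, i-m) .. min(n, i+m); the raw weight of gene
    j is m + 1 - |i - j| (linear decay from the centre, truncated at the
    chromosome ends); weights are normalized to sum to 1.
    """
    if not 1 <= i <= n:
        raise ValidationError(f"gene position {i} outside 1..{n}")
    j = np.arange(max(1, i - m), min(n, i + m) + 1)
    raw = (m + 1 - np.abs(i - j)).astype(float)
    return raw / raw.sum()


def smooth_chromosome(values: np.ndarray, m: int) -> np.ndarray:
    """Pyramidal moving average along the gene axis of a beads x genes block.

    Implemented as one convolution for the weighted sums and one for the
    truncated weight totals; equals the per-gene weighted average with
    :func:`pyramid_weights` exactly (up to float round-off).
    """
    values = np.asarray(values, dtype=float)
    if m == 0:
        return values.copy()
    kernel = (m + 1 - np.abs(np.arange(-m, m + 1))).astype(float)
    num = convolve1d(values, kernel, axis=-1, mode="constant", cval=0.0)
    den = convolve1d(np.ones(values.shape[-1]), kernel, mode="constant", cval=0.0)
    return num / den


def smooth_genome(
    intensities: IntensityMatrix, cfg: SmoothingConfig | None = None
) -> IntensityMatrix:
    """Apply pyramidal smoothing chromosome by chromosome, in karyotype order."""
    cfg = cfg or SmoothingConfig()
    if intensities.stage != "log_centered":
        raise ValidationError("smoothing expects log_centered intensities")
    out = intensities.values.copy()
    for chrom, genes in intensities.gene_order.chromosomes():
        n = len(genes)
        if n == 0:
            log.info("smooth: chromosome %s has no genes; skipped", chrom)
            continue
        m = half_window(n, cfg.window_k)
        out.loc[:, genes] = smooth_chromosome(out.loc[:, genes].to_numpy(), m)
    return IntensityMatrix(out, "smoothed", intensities.gene_order)


def recenter_and_rescale(
    smoothed: IntensityMatrix, reference_beads: pd.Index
) -> IntensityMatrix:
    """Turn smoothed log expression into relative expression intensities.

    First each bead is centred on its own mean smoothed intensity across
    genes — a per-bead baseline of zero intensity change that removes
    depth-driven global shifts (sparse beads sit systematically lower in
    log(TPM+1) space than deep beads). Then each gene is centred on its mean
    over reference beads, and the log2 transform is inverted. Reference beads
    end up with intensities centred on 1 (copy neutral).
    """
    if smoothed.stage != "smoothed":
        raise ValidationError("rescaling expects smoothed intensities")
    reference_beads = pd.Index(reference_beads)
    if len(reference_beads) == 0:
        raise ValidationError("reference population required")
    vals = smoothed.values.sub(smoothed.values.mean(axis=1), axis=0)
    vals = vals - vals.loc[reference_beads].mean(axis=0)
    return IntensityMatrix(np.exp2(vals), "rescaled", smoothed.gene_order)
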