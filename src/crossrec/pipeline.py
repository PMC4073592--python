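"""The full cross-recurrence pipeline: embed, distance, threshold, measure."""

from __future__ import annotations

from dataclasses import dataclass

from .embedding import (EmbeddingConfig, RecurrenceMatrix, apply_theiler_window,
                        cross_distance_matrix, embed_series, threshold_to_recurrence)
from .measures import RQAMeasures, compute_rqa_measures
from .series import as_timeseries

__all__ = ["crqa", "CRQAResult", "recurrence_matrix"]


@dataclass(frozen=True)
class CRQAResult:
    measures: RQAMeasures
    matrix: RecurrenceMatrix
    config: EmbeddingConfig


def recurrence_matrix(x, y, delay: int = 1, embed: int = 1, radius: float = 0.001,
                      tw: int = 0, normalize: str = "none", rescale: str = "none",
                      datatype: str = "continuous") -> RecurrenceMatrix:
    """Build the (Theiler-masked) cross-recurrence matrix of two series."""
    cfg = EmbeddingConfig(delay=delay, dim=embed, radius=radius,
                          normalize=normalize, rescale=rescale)
    tx = as_timeseries(x, datatype)
    ty = as_timeseries(y, datatype)
    ea = embed_series(tx, delay, embed, normalize=normalize)
    eb = embed_series(ty, delay, embed, normalize=normalize)
    D = cross_distance_matrix(ea, eb, rescale=rescale)
    R = threshold_to_recurrence(D, radius)
    return apply_theiler_window(R, tw)


def crqa(x, y, delay: int = 1, embed: int = 1, radius: float = 0.001, tw: int = 0,
         minline: int = 2, normalize: str = "none", rescale: str = "none",
         datatype: str = "continuous") -> CRQAResult:
    """Cross-recurrence quantification of two series.

    For categorical series (integer state codes) keep the defaults
    delay = embed = 1 and a near-zero radius, so that only exact state
    matches recur.  For continuous series, pick delay/embed/radius e.g.
    via :func:`crossrec.optimize.optimize_params`, and consider
    ``normalize="zscore"``.

    tw is the Theiler window: 0 (default, appropriate for two different
    series) keeps the main diagonal, 1 removes exactly the main
    diagonal — useful for auto-recurrence of a series with itself.
    """
    R = recurrence_matrix(x, y, delay=delay, embed=embed, radius=radius, tw=tw,
                          normalize=normalize, rescale=rescale, datatype=datatype)
    cfg = EmbeddingConfig(delay=delay, dim=embed, radius=radius,
                          normalize=normalize, rescale=rescale)
    return CRQAResult(compute_rqa_measures(R, minline=minline), R, cfg)
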