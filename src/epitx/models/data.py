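"""Assembly of model-ready arrays from tracks and annotations."""

from __future__ import annotations

import numpy as np
import pandas as pd

from epitx.signal import bin_signal, make_gene_windows
from epitx.tracks import DepthTrack


def build_promoter_matrix(
    tracks: dict[str, DepthTrack],
    annotations: pd.DataFrame,
    promoter_half_width: int = 3000,
    resolution: int = 100,
) -> tuple[np.ndarray, list[str]]:
    """Stack strand-oriented promoter windows into (N, n_marks, n_bins)."""
    marks = list(tracks)
    rows = []
    gene_ids = []
    for _, ann in annotations.iterrows():
        window = make_gene_windows(ann, "promoter", promoter_half_width=promoter_half_width)
        rows.append(
            [bin_signal(tracks[m], window, resolution).values for m in marks]
        )
        gene_ids.append(ann["gene_id"])
    return np.asarray(rows), gene_ids


def take_batch(inputs, idx):
    """Index into an input container (ndarray or anything with .take)."""
    if isinstance(inputs, np.ndarray):
        return inputs[idx]
    return inputs.take(idx)


def n_examples(inputs) -> int:
    if isinstance(inputs, np.ndarray):
        return len(inputs)
    return inputs.n
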