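"""Site-resolved solute-water distance distributions and cutoff suggestion.

Distances are measured from a solute oxygen site to every water hydrogen
(minimum image), excluding the covalent O-H of the water itself by
construction since only intermolecular pairs are formed.  The covalent bond
length (~0.10 nm) is therefore not part of the reported hydrogen-bond
distance, so the first hydration shell appears near 0.18 nm and the second
near 0.30 nm; the minimum between the two peaks is the natural hydrogen-bond
distance cutoff.

Distributions are raw counts (no shell-volume normalization); an optional
normalized view is provided.  The collection cutoff truncates the histogram
and is recorded on it, because a second-shell peak cut by the collection
window looks artificially sharp.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .errors import AnalysisError
from .graphs import _detect_solvent, _mi_delta
from .topology import Frame, SystemTopology

__all__ = ["DistanceHistogram", "distance_distribution", "suggest_cutoff"]


@dataclass
class DistanceHistogram:
    """Histogram of site...water-H distances below a collection cutoff."""

    site: str                 # site label, or "ALL" for every oxygen site
    bin_edges: np.ndarray     # nm, uniform
    counts: np.ndarray        # len(bin_edges) - 1
    n_frames: int
    collection_cutoff: float  # nm; the histogram is truncated here

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def normalized(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total else self.counts.astype(float)


def distance_distribution(frames: Sequence[Frame], topology: SystemTopology,
                          site: str = "ALL", collection_cutoff: float = 0.35,
                          bin_width: float = 0.005,
                          solvent: str | None = None,
                          box_edge: float | None = None) -> DistanceHistogram:
    """Histogram of minimum-image distances from solute oxygen site(s) to all
    water hydrogens, collected below ``collection_cutoff``."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if bin_width > collection_cutoff:
        raise ValueError("bin_width exceeds the collection cutoff")
    solvent = solvent or _detect_solvent(topology)

    site_serials: list[int] = []
    water_h_serials: list[int] = []
    for mi in topology.instances():
        if mi.template.name == solvent:
            water_h_serials.extend(
                mi.atom_offset + j + 1
                for j, el in enumerate(mi.template.elements) if el == "H")
        else:
            for label, local in mi.template.sites.items():
                if mi.template.elements[local] != "O":
                    continue
                if site == "ALL" or label == site:
                    site_serials.append(mi.atom_offset + local + 1)
    if not site_serials:
        raise AnalysisError(f"no oxygen site matching {site!r}")

    n_bins = int(np.ceil(collection_cutoff / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins, dtype=np.int64)
    a_idx = np.array(site_serials, dtype=np.intp) - 1
    b_idx = np.array(water_h_serials, dtype=np.intp) - 1
    for fr in frames:
        box = box_edge if box_edge is not None else (fr.box_edge or topology.box_edge)
        d, _ = _mi_delta(fr.coords[a_idx], fr.coords[b_idx], box)
        r = np.linalg.norm(d, axis=-1).ravel()
        r = r[r < collection_cutoff]
        counts += np.histogram(r, bins=edges)[0]
    return DistanceHistogram(site, edges, counts, len(frames), collection_cutoff)


def suggest_cutoff(hist: DistanceHistogram,
                   min_prominence_fraction: float = 0.05) -> float:
    """Suggest a hydrogen-bond distance cutoff from a bimodal distribution.

    The cutoff is the centre of the lowest-count bin strictly between the
    first two peaks (for a tie, the middle bin of the lowest run), i.e. the
    first-/second-shell minimum.  A histogram without two separated peaks
    raises :class:`AnalysisError` rather than guessing.
    """
    counts = hist.counts.astype(float)
    if counts.sum() == 0:
        raise AnalysisError("empty histogram: no interior minimum")
    prominence = counts.max() * min_prominence_fraction
    peaks, _ = find_peaks(np.concatenate(([-1.0], counts, [-1.0])),
                          prominence=prominence)
    peaks -= 1  # undo padding offset
    if len(peaks) < 2:
        raise AnalysisError(
            "distribution has no interior minimum between two peaks; "
            "cannot suggest a cutoff")
    lo, hi = int(peaks[0]), int(peaks[1])
    interior = counts[lo + 1:hi]
    if interior.size == 0:
        raise AnalysisError("peaks are adjacent; no interior minimum")
    low = np.flatnonzero(interior == interior.min()) + lo + 1
    best = int(low[len(low) // 2])  # middle of the lowest run
    return float(hist.bin_centers[best])
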