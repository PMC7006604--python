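"""Summary artifacts: superfamily count tables, insertion-age histograms and
fixed-count genome-window density tracks.

The density track divides the genome into a fixed total number of windows
(default 6,000) allocated to chromosomes proportionally to their length;
each feature is assigned to the window containing its midpoint.
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

SUPERFAMILIES = ("Gypsy", "Copia", "Unclassified")


def summarize_counts(elements: Sequence, young_threshold_mya: float = 2.0
                     ) -> pd.DataFrame:
    """Counts of dated elements per superfamily plus TOTAL, with a parallel
    column restricted to young (age < threshold, non-saturated) elements."""
    rows = []
    for fam in SUPERFAMILIES:
        fam_el = [e for e in elements if e.superfamily == fam]
        young = [e for e in fam_el
                 if not e.saturated and e.age_mya is not None
                 and e.age_mya < young_threshold_mya]
        rows.append((fam, len(fam_el), len(young)))
    total = sum(r[1] for r in rows)
    total_young = sum(r[2] for r in rows)
    rows.append(("TOTAL", total, total_young))
    return pd.DataFrame(rows, columns=["superfamily", "n_elements", "n_young"])


def age_histogram(elements: Sequence, bin_width_mya: float = 0.5) -> pd.DataFrame:
    """Per-superfamily insertion-age histogram, left-closed bins from 0.

    Saturated elements (undefined age) are excluded; the counts sum to the
    number of non-saturated elements.
    """
    if bin_width_mya <= 0:
        raise ValueError("bin_width_mya must be > 0")
    ages = {fam: [e.age_mya for e in elements
                  if e.superfamily == fam and not e.saturated and e.age_mya is not None]
            for fam in SUPERFAMILIES}
    all_ages = [a for v in ages.values() for a in v]
    n_bins = int(np.floor(max(all_ages) / bin_width_mya)) + 1 if all_ages else 1
    edges = np.arange(n_bins + 1) * bin_width_mya
    rows = []
    for i in range(n_bins):
        row = {"bin_start_mya": edges[i], "bin_end_mya": edges[i + 1]}
        for fam in SUPERFAMILIES:
            row[fam] = int(sum(edges[i] <= a < edges[i + 1] for a in ages[fam]))
        rows.append(row)
    return pd.DataFrame(rows)


def allocate_windows(chrom_lengths: Dict[str, int], n_windows: int) -> Dict[str, int]:
    """Largest-remainder allocation of *n_windows* across chromosomes,
    proportional to length; every chromosome receives at least one window."""
    if n_windows < len(chrom_lengths):
        raise ValueError("n_windows must be >= number of chromosomes")
    chroms = sorted(chrom_lengths)
    total = sum(chrom_lengths.values())
    quotas = {c: n_windows * chrom_lengths[c] / total for c in chroms}
    alloc = {c: max(1, int(np.floor(quotas[c]))) for c in chroms}
    leftover = n_windows - sum(alloc.values())
    remainders = sorted(chroms, key=lambda c: (-(quotas[c] - np.floor(quotas[c])), c))
    i = 0
    while leftover > 0:
        alloc[remainders[i % len(chroms)]] += 1
        leftover -= 1
        i += 1
    while leftover < 0:  # possible when the max(1,...) floor overshoots
        donor = max(chroms, key=lambda c: alloc[c])
        alloc[donor] -= 1
        leftover += 1
    return alloc


def density_windows(features: Iterable[Tuple[str, int, int]],
                    chrom_lengths: Dict[str, int],
                    n_windows: int = 6000,
                    feature_class: str = "all") -> pd.DataFrame:
    """Midpoint-assigned feature counts over genome-tiling windows.

    *features* yields (chrom, start, end) intervals.  Windows tile each
    chromosome without overlap; a midpoint exactly on a boundary belongs to
    the right-hand (half-open) window.  The per-window counts sum to the
    number of features on known chromosomes.
    """
    alloc = allocate_windows(chrom_lengths, n_windows)
    rows = []
    boundaries: Dict[str, np.ndarray] = {}
    index_offset: Dict[str, int] = {}
    offset = 0
    for chrom in sorted(chrom_lengths):
        m = alloc[chrom]
        L = chrom_lengths[chrom]
        edges = np.floor(np.arange(m + 1) * L / m).astype(int)
        boundaries[chrom] = edges
        index_offset[chrom] = offset
        for i in range(m):
            rows.append({"feature_class": feature_class, "chrom": chrom,
                         "window_index": offset + i,
                         "start": int(edges[i]), "end": int(edges[i + 1]),
                         "count": 0})
        offset += m
    df = pd.DataFrame(rows)
    counts = df["count"].to_numpy()
    for chrom, start, end in features:
        if chrom not in boundaries:
            continue
        mid = (start + end) // 2
        edges = boundaries[chrom]
        w = int(np.searchsorted(edges, mid, side="right")) - 1
        w = min(max(w, 0), len(edges) - 2)
        counts[index_offset[chrom] + w] += 1
    df["count"] = counts
    return df


def plot_age_histogram(hist: pd.DataFrame, path: str) -> None:
    """Optional stacked-bar rendering of :func:`age_histogram` output."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    bottom = np.zeros(len(hist))
    width = (hist.bin_end_mya - hist.bin_start_mya).to_numpy()
    for fam in SUPERFAMILIES:
        ax.bar(hist.bin_start_mya, hist[fam], width=width, align="edge",
               bottom=bottom, label=fam)
        bottom += hist[fam].to_numpy()
    ax.set_xlabel("Insertion age (Mya)")
    ax.set_ylabel("Elements")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_density(track: pd.DataFrame, path: str,
                 title: Optional[str] = None) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 3))
    ax.plot(track.window_index, track["count"], lw=0.8)
    ax.set_xlabel("Genome window")
    ax.set_ylabel("Features / window")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
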