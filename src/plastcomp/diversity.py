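"""Sliding-window nucleotide diversity (Pi) over alignment columns and
hotspot calling.

Pi for a window is the average, over all row pairs, of (differing sites /
valid sites), where a site is valid for a pair when both rows carry a
non-gap, non-N base there. Windows slide over alignment columns (default
600-bp windows, 200-bp step); a trailing partial window is dropped. Hotspots
are merged runs of adjacent windows whose Pi exceeds a threshold (0.008 is
the customary within-genus cutoff, 0.015 between genera).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from ._util import ParameterError
from .alignment import AlignmentMap, PairwiseAlignment, build_map
from .io_genomes import AnnotatedGenome, loci_in_range


@dataclass(frozen=True)
class Window:
    start_col: int
    end_col: int
    midpoint_col: int
    valid_sites: float      # mean valid sites across row pairs
    pi: float
    no_valid_sites: bool = False


@dataclass
class DiversityProfile:
    window_len: int
    step: int
    n_rows: int
    windows: list[Window] = field(default_factory=list)

    @property
    def pi_values(self) -> np.ndarray:
        return np.array([w.pi for w in self.windows], dtype=float)

    def mean_pi(self) -> float:
        return float(self.pi_values.mean()) if self.windows else 0.0

    def max_pi(self) -> float:
        return float(self.pi_values.max()) if self.windows else 0.0


@dataclass(frozen=True)
class Hotspot:
    threshold: float
    start_col: int
    end_col: int
    ref_start: int
    ref_end: int
    max_pi: float
    labels: tuple[str, ...]


def window_pi(
    aln: PairwiseAlignment, window_len: int = 600, step: int = 200
) -> DiversityProfile:
    """Per-window pairwise nucleotide diversity across alignment columns."""
    if window_len < 1 or step < 1:
        raise ParameterError("window_len and step must be >= 1")
    arrs = [np.frombuffer(r.encode(), dtype="S1") for r in aln.rows]
    pairs = list(combinations(range(len(arrs)), 2))
    cum_valid, cum_diff = [], []
    for i, j in pairs:
        a, b = arrs[i], arrs[j]
        valid = (a != b"-") & (b != b"-") & (a != b"N") & (b != b"N")
        diff = valid & (a != b)
        cum_valid.append(np.concatenate(([0], np.cumsum(valid))))
        cum_diff.append(np.concatenate(([0], np.cumsum(diff))))
    profile = DiversityProfile(window_len, step, len(arrs))
    for start in range(0, aln.width - window_len + 1, step):
        end = start + window_len
        pis, valids = [], []
        for cv, cd in zip(cum_valid, cum_diff):
            v = int(cv[end] - cv[start])
            d = int(cd[end] - cd[start])
            valids.append(v)
            if v > 0:
                pis.append(d / v)
        flagged = not pis
        pi = float(np.mean(pis)) if pis else 0.0
        profile.windows.append(
            Window(start, end, start + window_len // 2,
                   float(np.mean(valids)), pi, flagged)
        )
    return profile


def call_hotspots(
    profile: DiversityProfile,
    threshold: float,
    amap: AlignmentMap | None = None,
    ref_genome: AnnotatedGenome | None = None,
    ref_row: int = 0,
) -> list[Hotspot]:
    """Merged runs of adjacent windows with pi > threshold, labelled with the
    reference loci they overlap (when annotation is available)."""
    if threshold <= 0:
        raise ParameterError("hotspot threshold must be > 0")
    runs: list[list[Window]] = []
    prev_idx = None
    for idx, w in enumerate(profile.windows):
        if w.pi > threshold:
            if prev_idx is not None and idx == prev_idx + 1:
                runs[-1].append(w)
            else:
                runs.append([w])
            prev_idx = idx
    out: list[Hotspot] = []
    for run in runs:
        c1, c2 = run[0].start_col, run[-1].end_col
        r1 = r2 = -1
        labels: tuple[str, ...] = ()
        if amap is not None:
            r1 = max(amap.ref_pos_at(ref_row, c1), 0)
            r2 = amap.ref_pos_at(ref_row, c2 - 1) + 1
            if ref_genome is not None:
                labels = tuple(loci_in_range(ref_genome, r1, r2))
        out.append(
            Hotspot(threshold, c1, c2, r1, r2,
                    max(w.pi for w in run), labels)
        )
    return out


def write_profile_tsv(profile: DiversityProfile, path, amap=None, ref_row: int = 0) -> None:
    """Profile TSV: window midpoint (alignment column and, when a map is
    given, reference coordinate), mean valid sites, Pi to 5 decimals."""
    with open(path, "w") as fh:
        fh.write("midpoint_col\tmidpoint_ref\tvalid_sites\tpi\n")
        for w in profile.windows:
            mid_ref = amap.ref_pos_at(ref_row, w.midpoint_col) + 1 if amap else ""
            fh.write(f"{w.midpoint_col}\t{mid_ref}\t{w.valid_sites:.1f}\t{w.pi:.5f}\n")


def write_hotspots(hotspots: list[Hotspot], ref_id: str, bed_path, tsv_path) -> None:
    with open(bed_path, "w") as fh:
        for h in hotspots:
            name = ",".join(h.labels) or "hotspot"
            fh.write(f"{ref_id}\t{h.ref_start}\t{h.ref_end}\t{name}\t{h.max_pi:.5f}\n")
    with open(tsv_path, "w") as fh:
        fh.write("ref_start\tref_end\tstart_col\tend_col\tmax_pi\tlabels\n")
        for h in hotspots:
            fh.write(
                f"{h.ref_start + 1}\t{h.ref_end}\t{h.start_col}\t{h.end_col}"
                f"\t{h.max_pi:.5f}\t{','.join(h.labels)}\n"
            )


def plot_profile(profiles, labels, path, thresholds=()):
    """Two-panel-style Pi plot (optional; requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(len(profiles), 1, figsize=(10, 3 * len(profiles)),
                             squeeze=False)
    for ax, prof, lab in zip(axes[:, 0], profiles, labels):
        mids = [w.midpoint_col for w in prof.windows]
        ax.plot(mids, prof.pi_values, lw=0.8)
        for t in thresholds:
            ax.axhline(t, color="red", ls="--", lw=0.6)
        ax.set_ylabel("Pi")
        ax.set_title(lab)
    axes[-1, 0].set_xlabel("alignment column (window midpoint)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
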