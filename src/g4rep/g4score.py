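"""Residue-level localization of candidate G4-binding regions.

A G4-binder's interacting subsequence is typically an intrinsically
disordered stretch enriched in Gly/Ser/Tyr/Phe/Arg (the RGG-box
neighbourhood).  The window score combines both signals: for every length-n
window the composite

    G = (mean disorder of the window) * (G/S/Y/F/R density of the window)

ranges from 0 up to the window-mean disorder, peaking where flexibility and
the characteristic composition coincide.  A gate then silences windows whose
G falls below a threshold T, and passes the sequence-level binding
probability B through everywhere else, so the gated track takes exactly the
two values {0, B}.  Contiguous passing windows are merged into candidate
regions.  All coordinates in file output are 1-based inclusive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: Residues characteristic of G4-binding regions.
MOTIF_SET = frozenset("GSYFR")

DEFAULT_WINDOW = 15
DEFAULT_THRESHOLD_PERCENTILE = 60.0


@dataclass(frozen=True)
class DisorderProfile:
    """Per-residue disorder scores in [0, 1], one per residue of the protein."""

    seq_id: str
    d: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))
        if self.d.ndim != 1 or self.d.size < 1:
            raise ValueError(f"{self.seq_id}: disorder profile must be a 1-D vector")
        if np.any((self.d < 0) | (self.d > 1)):
            raise ValueError(f"{self.seq_id}: disorder values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.d.size


@dataclass(frozen=True)
class Window:
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    mean_disorder: float
    motif_density: float
    G: float


@dataclass
class WindowScoreTrack:
    seq_id: str
    n: int
    windows: list[Window]
    motif_set: frozenset = MOTIF_SET


@dataclass
class GatedTrack:
    track: WindowScoreTrack
    T: float
    B: float
    gated: np.ndarray  # per-window, values in {0, B}
    regions: list[tuple[int, int]] = field(default_factory=list)  # merged, 1-based


def motif_density(window: str, motif_set: frozenset = MOTIF_SET) -> float:
    """Fraction of window residues belonging to the motif set."""
    if len(window) < 1:
        raise ValueError("window must be non-empty")
    return sum(1 for aa in window if aa in motif_set) / len(window)


def g4rep_score(d_window, window: str, n: int | None = None,
                motif_set: frozenset = MOTIF_SET) -> float:
    """Composite window score: window-mean disorder times motif density.

    The product form keeps the score between 0 and the window's mean
    disorder, vanishing when either signal is absent, and is monotone in each
    disorder value and in motif-set membership.
    """
    d_window = np.asarray(d_window, dtype=float)
    n = n if n is not None else len(window)
    if len(window) != n or d_window.size != n:
        raise ValueError("disorder values and window residues must both have length n")
    return float(d_window.mean() * motif_density(window, motif_set))


def gate(G: float, B: float, T: float) -> float:
    """0 when G < T; B when G >= T (the boundary passes)."""
    if not (0.0 <= B <= 1.0):
        raise ValueError(f"binding score B out of [0,1]: {B}")
    return B if G >= T else 0.0


def score_protein(
    residues: str,
    profile: DisorderProfile,
    B: float,
    n: int = DEFAULT_WINDOW,
    T: float | None = None,
    threshold_percentile: float = DEFAULT_THRESHOLD_PERCENTILE,
    motif_set: frozenset = MOTIF_SET,
) -> GatedTrack:
    """Slide a length-n window over the protein and gate the resulting track.

    ``T`` defaults to the given percentile of the protein's own window scores,
    adapting the gate to each protein's disorder level; pass an absolute ``T``
    to override.  Sequences shorter than ``n`` are scored as a single window
    spanning the whole sequence (with a warning).
    """
    L = len(residues)
    if len(profile) != L:
        raise ValueError(
            f"{profile.seq_id}: profile length {len(profile)} != sequence length {L}"
        )
    if L < n:
        logger.warning("%s: sequence (L=%d) shorter than window n=%d; using n=L",
                       profile.seq_id, L, n)
        n = L

    windows: list[Window] = []
    for start in range(L - n + 1):
        sub = residues[start : start + n]
        d_sub = profile.d[start : start + n]
        rho = motif_density(sub, motif_set)
        md = float(d_sub.mean())
        windows.append(
            Window(start + 1, start + n, md, rho, g4rep_score(d_sub, sub, n, motif_set))
        )
    track = WindowScoreTrack(profile.seq_id, n, windows, motif_set)

    scores = np.array([w.G for w in windows])
    if T is None:
        T = float(np.percentile(scores, threshold_percentile))
    gated = np.array([gate(w.G, B, T) for w in windows])

    # Merge runs of consecutive passing windows: region = start of the first
    # window in the run, end of the last.
    regions: list[tuple[int, int]] = []
    prev_idx = None
    for idx, (w, g) in enumerate(zip(windows, gated)):
        if g == 0.0:
            continue
        if prev_idx is not None and idx == prev_idx + 1:
            regions[-1] = (regions[-1][0], w.end)
        else:
            regions.append((w.start, w.end))
        prev_idx = idx
    return GatedTrack(track, T, B, gated, regions)


def top_window(track: WindowScoreTrack) -> Window:
    """The window with the maximal composite score (first on ties)."""
    return max(track.windows, key=lambda w: (w.G, -w.start))


def read_disorder_tsv(path) -> dict[str, DisorderProfile]:
    """Read per-residue disorder profiles from a TSV with columns
    ``seq_id, position (1-based), residue, score``; '#' lines are comments."""
    values: dict[str, list[tuple[int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "seq_id":
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected seq_id, position, residue, score")
            values.setdefault(parts[0], []).append((int(parts[1]), float(parts[3])))
    profiles = {}
    for sid, rows in values.items():
        rows.sort()
        positions = [p for p, _ in rows]
        if positions != list(range(1, len(rows) + 1)):
            raise ValueError(f"{sid}: disorder positions are not contiguous from 1")
        profiles[sid] = DisorderProfile(sid, np.array([s for _, s in rows]))
    return profiles


def write_disorder_tsv(profiles: dict[str, DisorderProfile], residues: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        fh.write("# per-residue disorder scores; coordinates 1-based inclusive\n")
        fh.write("seq_id\tposition\tresidue\tscore\n")
        for sid, prof in profiles.items():
            seq = residues[sid]
            for i, s in enumerate(prof.d):
                fh.write(f"{sid}\t{i + 1}\t{seq[i]}\t{s:.4f}\n")


def write_track_tsv(gt: GatedTrack, path, append: bool = False) -> None:
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        if not append:
            fh.write("# window score track; coordinates 1-based inclusive\n")
            fh.write("seq_id\tstart\tend\tmean_disorder\trho\tG\tgated\n")
        for w, g in zip(gt.track.windows, gt.gated):
            fh.write(
                f"{gt.track.seq_id}\t{w.start}\t{w.end}\t{w.mean_disorder:.4f}\t"
                f"{w.motif_density:.4f}\t{w.G:.4f}\t{g:.4f}\n"
            )


def write_regions_tsv(tracks: list[GatedTrack], path) -> None:
    with open(path, "w") as fh:
        fh.write("# merged candidate regions; coordinates 1-based inclusive\n")
        fh.write("seq_id\tstart\tend\tB\tT\n")
        for gt in tracks:
            for start, end in gt.regions:
                fh.write(f"{gt.track.seq_id}\t{start}\t{end}\t{gt.B:.4f}\t{gt.T:.4f}\n")


def plot_track(gt: GatedTrack, profile: DisorderProfile, path) -> None:
    """Plot the window score and disorder profile along the sequence."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = [(w.start + w.end) / 2 for w in gt.track.windows]
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.plot(np.arange(1, len(profile) + 1), profile.d, color="goldenrod",
            label="disorder", alpha=0.8)
    ax.plot(centers, [w.G for w in gt.track.windows], color="steelblue",
            label="window score G")
    ax.axhline(gt.T, color="grey", linestyle=":", label=f"T={gt.T:.2f}")
    for start, end in gt.regions:
        ax.axvspan(start, end, color="steelblue", alpha=0.15)
    ax.set_xlabel("residue position (1-based)")
    ax.set_ylabel("score")
    ax.set_title(f"{gt.track.seq_id}  (B={gt.B:.2f})")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
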