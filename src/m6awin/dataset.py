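"""Windowed-dataset construction from transcripts and single-base sites.

Pipeline: merge clustered sites (single-linkage within `merge_distance`,
representative = lower-median member), place one positive window per
representative with the site at a uniformly random in-window location,
search for the closest m6A-free negative-control window at offsets
``gap + k*stride`` up/downstream, then split windows at random into
train / validation / test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import SiteRecord, WindowRecord, write_fasta, write_windows


@dataclass
class BuilderConfig:
    window_size: int = 101
    merge_distance: int = 50
    negative_gap: int = 100
    negative_stride: int = 10
    negative_steps: int = 100
    train_fraction: float = 0.8
    val_fraction_of_train: float = 0.125
    group_by_transcript: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        for name in ("negative_gap", "negative_stride", "negative_steps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class WindowedDataset:
    windows: list[WindowRecord]
    split: dict[str, str]  # window_id -> train | val | test
    config: BuilderConfig
    counts: dict[str, int] = field(default_factory=dict)

    def subset(self, which: str) -> list[WindowRecord]:
        return [w for w in self.windows if self.split[w.window_id] == which]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for which in ("train", "val", "test"):
            subset = self.subset(which)
            write_windows(subset, outdir / f"{which}.windows.tsv")
            write_fasta(
                {w.window_id: w.sequence for w in subset},
                outdir / f"{which}.fa",
            )
        meta = {
            "config": asdict(self.config),
            "counts": self.counts,
            "seed": self.config.seed,
        }
        (outdir / "metadata.json").write_text(json.dumps(meta, indent=2) + "\n")


def merge_sites(positions: list[int], merge_distance: int) -> list[int]:
    """Collapse clustered sites to one representative per cluster.

    Single-linkage chaining: consecutive sites <= `merge_distance` apart
    join one cluster; the representative is the cluster's median member
    (lower median for even-sized clusters).
    """
    if not positions:
        return []
    positions = sorted(positions)
    representatives: list[int] = []
    cluster = [positions[0]]
    for pos in positions[1:]:
        if pos - cluster[-1] <= merge_distance:
            cluster.append(pos)
        else:
            representatives.append(cluster[(len(cluster) - 1) // 2])
            cluster = [pos]
    representatives.append(cluster[(len(cluster) - 1) // 2])
    return representatives


def place_positive_window(
    transcript_len: int, site: int, config: BuilderConfig, rng: np.random.Generator
) -> tuple[int, int]:
    """Choose a uniformly random window containing `site`.

    The window has length ``min(window_size, transcript_len)`` and is
    clamped to the transcript when the site is near a terminus.
    Returns (start, end), 0-based half-open.
    """
    if transcript_len < 1:
        raise ValueError(f"transcript_len must be >= 1, got {transcript_len}")
    if not 0 <= site < transcript_len:
        raise ValueError(f"site {site} outside transcript of length {transcript_len}")
    wlen = min(config.window_size, transcript_len)
    lo = max(0, site - wlen + 1)
    hi = min(site, transcript_len - wlen)
    start = int(rng.integers(lo, hi + 1))
    return start, start + wlen


def _span_has_site(sorted_sites: np.ndarray, start: int, end: int) -> bool:
    i = int(np.searchsorted(sorted_sites, start, side="left"))
    return i < len(sorted_sites) and sorted_sites[i] < end


def find_negative_window(
    positive_start: int,
    window_len: int,
    transcript_len: int,
    sites_on_transcript: list[int],
    config: BuilderConfig,
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    """Find the closest site-free window near a positive one.

    Candidate starts are ``positive_start +/- (gap + k*stride)`` for
    k = 0..steps-1; a candidate must lie fully inside the transcript and
    contain none of the original (pre-merge) sites.  The upstream and
    downstream candidates at equal distance tie; ties are broken
    uniformly at random.  Returns None when no candidate is feasible.
    """
    sorted_sites = np.asarray(sorted(sites_on_transcript), dtype=np.int64)

    def valid(start: int) -> bool:
        return (
            start >= 0
            and start + window_len <= transcript_len
            and not _span_has_site(sorted_sites, start, start + window_len)
        )

    for k in range(config.negative_steps):
        offset = config.negative_gap + k * config.negative_stride
        up, down = positive_start - offset, positive_start + offset
        up_ok, down_ok = valid(up), valid(down)
        if up_ok and down_ok:
            start = up if rng.random() < 0.5 else down
        elif up_ok:
            start = up
        elif down_ok:
            start = down
        else:
            continue
        return start, start + window_len
    return None


def build_dataset(
    fasta: dict[str, str], sites: list[SiteRecord], config: BuilderConfig
) -> WindowedDataset:
    """Build the full labeled window set plus split assignment.

    One positive window per merged site, at most one negative control
    per positive, split at the window level.  Fully deterministic for a
    given seed.
    """
    offenders = [
        f"{s.transcript_id}:{s.position}"
        for s in sites
        if s.transcript_id not in fasta or s.position >= len(fasta[s.transcript_id])
    ]
    if offenders:
        raise ValueError(
            "sites beyond transcript end or on missing transcripts: "
            + ", ".join(offenders)
        )

    rng = np.random.default_rng(config.seed)
    by_transcript: dict[str, list[int]] = {}
    for s in sites:
        by_transcript.setdefault(s.transcript_id, []).append(s.position)

    windows: list[WindowRecord] = []
    n_pos = n_neg = 0
    for transcript_id in sorted(by_transcript):
        seq = fasta[transcript_id]
        tlen = len(seq)
        original = sorted(set(by_transcript[transcript_id]))
        for rep in merge_sites(original, config.merge_distance):
            start, end = place_positive_window(tlen, rep, config, rng)
            offsets = [p - start for p in original if start <= p < end]
            windows.append(
                WindowRecord(
                    window_id=f"pos_{transcript_id}_{rep}",
                    transcript_id=transcript_id,
                    start=start,
                    end=end,
                    sequence=seq[start:end],
                    label="positive",
                    site_offsets=offsets,
                )
            )
            n_pos += 1
            neg = find_negative_window(
                start, end - start, tlen, original, config, rng
            )
            if neg is not None:
                nstart, nend = neg
                windows.append(
                    WindowRecord(
                        window_id=f"neg_{transcript_id}_{rep}",
                        transcript_id=transcript_id,
                        start=nstart,
                        end=nend,
                        sequence=seq[nstart:nend],
                        label="negative",
                        site_offsets=[],
                    )
                )
                n_neg += 1

    split = _assign_split(windows, config, rng)
    counts = {
        "positives": n_pos,
        "negatives": n_neg,
        "train": sum(1 for v in split.values() if v == "train"),
        "val": sum(1 for v in split.values() if v == "val"),
        "test": sum(1 for v in split.values() if v == "test"),
    }
    return WindowedDataset(windows=windows, split=split, config=config, counts=counts)


def _assign_split(
    windows: list[WindowRecord], config: BuilderConfig, rng: np.random.Generator
) -> dict[str, str]:
    """Random window-level split: test, then validation carved from train.

    With ``group_by_transcript`` all windows of one transcript land in
    the same split (off by default).
    """
    if not windows:
        return {}
    if config.group_by_transcript:
        units = sorted({w.transcript_id for w in windows})
        membership = {u: [w.window_id for w in windows if w.transcript_id == u]
                      for u in units}
    else:
        units = [w.window_id for w in windows]
        membership = {u: [u] for u in units}
    order = [units[i] for i in rng.permutation(len(units))]
    n_test = int(round((1.0 - config.train_fraction) * len(order)))
    test_units = order[:n_test]
    train_units = order[n_test:]
    n_val = int(round(config.val_fraction_of_train * len(train_units)))
    val_units = train_units[:n_val]
    split: dict[str, str] = {}
    for u in test_units:
        for wid in membership[u]:
            split[wid] = "test"
    for u in val_units:
        for wid in membership[u]:
            split[wid] = "val"
    for u in train_units[n_val:]:
        for wid in membership[u]:
            split[wid] = "train"
    return split


def intersect_sites(a: list[SiteRecord], b: list[SiteRecord]) -> list[SiteRecord]:
    """Sites present in both lists by exact (transcript, position) match."""
    keys = {(s.transcript_id, s.position) for s in b}
    return [s for s in a if (s.transcript_id, s.position) in keys]
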