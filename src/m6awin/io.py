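"""Readers and writers for every on-disk representation the tool touches.

Conventions (documented loudly because upstream formats are ambiguous):

* All coordinates are 0-based, half-open ``[start, end)``.
* Site lists are transcript-oriented (5'->3' sense).  BED input with a
  minus strand is rejected: pre-orient your transcripts.
* The internal alphabet is A, C, G, U; T is accepted on input and
  converted to U.
"""

from __future__ import annotations

import io as _stdio
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

CHECKPOINT_VERSION = 1


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


class CheckpointError(ValueError):
    """Unreadable, truncated, or incompatible model checkpoint."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass
class SiteRecord:
    """A single-base modification site, transcript-relative, 0-based."""

    transcript_id: str
    position: int
    source_tag: str = ""


@dataclass
class TranscriptStructure:
    transcript_id: str
    length: int
    last_exon_start: int
    utr3_start: int

    def __post_init__(self):
        if not 0 <= self.last_exon_start <= self.utr3_start <= self.length:
            raise FormatError(
                f"{self.transcript_id}: require 0 <= last_exon_start "
                f"<= utr3_start <= length, got ({self.last_exon_start}, "
                f"{self.utr3_start}, {self.length})"
            )

    @property
    def utr3_length(self) -> int:
        return self.length - self.utr3_start


@dataclass
class WindowRecord:
    """A labeled fixed-size window with provenance coordinates."""

    window_id: str
    transcript_id: str
    start: int
    end: int
    sequence: str
    label: str  # "positive" | "negative"
    site_offsets: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.label not in ("positive", "negative"):
            raise FormatError(f"bad label {self.label!r}")
        if (self.label == "positive") != bool(self.site_offsets):
            raise FormatError(
                f"{self.window_id}: label={self.label} inconsistent with "
                f"site_offsets={self.site_offsets}"
            )
        span = self.end - self.start
        for off in self.site_offsets:
            if not 0 <= off < span:
                raise FormatError(
                    f"{self.window_id}: site offset {off} outside [0, {span})"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def normalize_sequence(seq: str) -> str:
    return seq.upper().replace("T", "U")


def read_fasta(path) -> dict[str, str]:
    """Read FASTA into {id: sequence}; uppercases and converts T to U."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise FormatError(f"duplicate FASTA id: {record.id}")
        sequences[record.id] = normalize_sequence(str(record.seq))
    if not sequences:
        raise FormatError(f"no FASTA records found in {path}")
    return sequences


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# site lists
# ---------------------------------------------------------------------------

def read_sites(path, fasta: dict[str, str] | None = None) -> list[SiteRecord]:
    """Read sites from 2/3-column TSV or BED6.

    TSV columns: transcript_id, position (0-based), optional source tag.
    BED6: the site is the 0-based `start`; strand must be "+".
    Positions are validated against `fasta` when one is supplied.
    """
    records: list[SiteRecord] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) >= 6:  # BED6
                strand = fields[5]
                if strand == "-" or strand == "−":
                    raise FormatError(
                        f"{path} line {lineno}: minus-strand BED record; "
                        "pre-orient transcripts to the sense strand"
                    )
                if strand != "+":
                    raise FormatError(
                        f"{path} line {lineno}: bad strand {strand!r}"
                    )
                rec = SiteRecord(fields[0], int(fields[1]), fields[3])
            elif len(fields) >= 2:
                tag = fields[2] if len(fields) > 2 else ""
                rec = SiteRecord(fields[0], int(fields[1]), tag)
            else:
                raise FormatError(f"{path} line {lineno}: expected >= 2 columns")
            if rec.position < 0:
                raise FormatError(
                    f"{path} line {lineno}: negative position {rec.position}"
                )
            records.append(rec)
    if fasta is not None:
        offenders = [
            f"{r.transcript_id}:{r.position}"
            for r in records
            if r.transcript_id not in fasta
            or r.position >= len(fasta[r.transcript_id])
        ]
        if offenders:
            raise FormatError(
                "sites beyond transcript end or on unknown transcripts: "
                + ", ".join(offenders)
            )
    return records


def write_sites(records: list[SiteRecord], path) -> None:
    with open(path, "w") as handle:
        for r in records:
            handle.write(f"{r.transcript_id}\t{r.position}\t{r.source_tag}\n")


# ---------------------------------------------------------------------------
# transcript structure
# ---------------------------------------------------------------------------

def read_structures(path) -> dict[str, TranscriptStructure]:
    structures: dict[str, TranscriptStructure] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and not fields[1].lstrip("-").isdigit():
                continue  # header
            if len(fields) < 4:
                raise FormatError(f"{path} line {lineno}: expected 4 columns")
            st = TranscriptStructure(
                fields[0], int(fields[1]), int(fields[2]), int(fields[3])
            )
            structures[st.transcript_id] = st
    return structures


def write_structures(structures: dict[str, TranscriptStructure], path) -> None:
    with open(path, "w") as handle:
        handle.write("transcript_id\tlength\tlast_exon_start\tutr3_start\n")
        for st in structures.values():
            handle.write(
                f"{st.transcript_id}\t{st.length}\t{st.last_exon_start}"
                f"\t{st.utr3_start}\n"
            )


# ---------------------------------------------------------------------------
# windowed datasets
# ---------------------------------------------------------------------------

_WINDOW_HEADER = "window_id\ttranscript_id\tstart\tend\tlabel\tsite_offsets\tsequence"


def write_windows(windows: list[WindowRecord], path) -> None:
    with open(path, "w") as handle:
        handle.write(_WINDOW_HEADER + "\n")
        for w in windows:
            offsets = ",".join(str(o) for o in w.site_offsets)
            handle.write(
                f"{w.window_id}\t{w.transcript_id}\t{w.start}\t{w.end}"
                f"\t{w.label}\t{offsets}\t{w.sequence}\n"
            )


def read_windows(path) -> list[WindowRecord]:
    windows: list[WindowRecord] = []
    with open(path) as handle:
        header = handle.readline().rstrip("\n")
        if header != _WINDOW_HEADER:
            raise FormatError(f"{path}: unexpected window-file header")
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            offsets = [int(x) for x in fields[5].split(",") if x]
            windows.append(
                WindowRecord(
                    window_id=fields[0],
                    transcript_id=fields[1],
                    start=int(fields[2]),
                    end=int(fields[3]),
                    label=fields[4],
                    site_offsets=offsets,
                    sequence=fields[6],
                )
            )
    return windows


# ---------------------------------------------------------------------------
# predictions / saliency tracks
# ---------------------------------------------------------------------------

def write_predictions(rows: list[tuple[str, float, str]], path) -> None:
    """rows: (window_id, score, confidence_tier)."""
    with open(path, "w") as handle:
        handle.write("window_id\tscore\tconfidence_tier\n")
        for window_id, score, tier in rows:
            handle.write(f"{window_id}\t{score:.6f}\t{tier}\n")


def write_saliency_tsv(tracks, path) -> None:
    """tracks: iterable of objects with window_id, sequence, scores."""
    with open(path, "w") as handle:
        handle.write("window_id\tposition\tbase\tsaliency_score\n")
        for track in tracks:
            for pos, (base, score) in enumerate(zip(track.sequence, track.scores)):
                handle.write(f"{track.window_id}\t{pos}\t{base}\t{score:.6g}\n")


# ---------------------------------------------------------------------------
# MEME minimal motif format
# ---------------------------------------------------------------------------

def write_meme(motifs, path, alphabet: str = "ACGU") -> None:
    """Write motifs in MEME minimal format.

    `motifs` is a list of objects with ``filter_index``, ``pwm`` (l x 4,
    row-stochastic) and ``support``.  Rows failing the sum-to-one check
    (1e-6) abort the write, naming the motif and row.
    """
    lines = ["MEME version 4", "", f"ALPHABET= {alphabet}", ""]
    for motif in motifs:
        pwm = np.asarray(motif.pwm, dtype=float)
        for row_index, row in enumerate(pwm):
            if abs(row.sum() - 1.0) > 1e-6:
                raise FormatError(
                    f"motif filter_{motif.filter_index} row {row_index} "
                    f"sums to {row.sum():.6f}, not 1"
                )
        lines.append(f"MOTIF filter_{motif.filter_index}")
        lines.append(
            f"letter-probability matrix: alength= 4 w= {pwm.shape[0]} "
            f"nsites= {motif.support} E= 0"
        )
        for row in pwm:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")
    with open(path, "w") as handle:
        handle.write("\n".join(lines).rstrip("\n") + "\n")


def parse_meme(path) -> dict[str, np.ndarray]:
    """Parse the MEME minimal format back to {motif_name: pwm}.

    Bundled so tests can validate the writer without the MEME suite.
    """
    motifs: dict[str, np.ndarray] = {}
    with open(path) as handle:
        lines = [line.rstrip("\n") for line in handle]
    if not lines or not lines[0].startswith("MEME version"):
        raise FormatError(f"{path}: missing MEME version line")
    i = 0
    while i < len(lines):
        if lines[i].startswith("MOTIF"):
            name = lines[i].split()[1]
            i += 1
            while i < len(lines) and not lines[i].startswith(
                "letter-probability matrix"
            ):
                i += 1
            if i == len(lines):
                raise FormatError(f"motif {name}: missing matrix header")
            width = int(lines[i].split("w=")[1].split()[0])
            rows = []
            for j in range(width):
                rows.append([float(v) for v in lines[i + 1 + j].split()])
            motifs[name] = np.array(rows)
            i += width + 1
        else:
            i += 1
    return motifs


# ---------------------------------------------------------------------------
# model checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model_state: dict[str, np.ndarray], config: dict,
                    metrics: dict, path) -> None:
    """Save weights + config + metrics into one versioned .npz archive."""
    meta = json.dumps(
        {"format_version": CHECKPOINT_VERSION, "config": config,
         "metrics": metrics},
        sort_keys=True,
    )
    arrays = {f"w::{k}": np.asarray(v) for k, v in model_state.items()}
    arrays["__meta__"] = np.array(meta)
    with open(path, "wb") as handle:
        np.savez(handle, **arrays)


def load_checkpoint(path, expect_window_size: int | None = None):
    """Load a checkpoint; returns (model_state, config, metrics)."""
    try:
        archive = np.load(path, allow_pickle=False)
        names = set(archive.files)
    except (zipfile.BadZipFile, OSError, ValueError, EOFError) as exc:
        raise CheckpointError(f"corrupt or unreadable checkpoint {path}: {exc}")
    if "__meta__" not in names:
        raise CheckpointError(f"{path}: not a recognized checkpoint (no metadata)")
    meta = json.loads(str(archive["__meta__"]))
    version = meta.get("format_version")
    if version != CHECKPOINT_VERSION:
        raise CheckpointError(
            f"{path}: checkpoint format version {version} != "
            f"supported {CHECKPOINT_VERSION}"
        )
    config = meta["config"]
    if (
        expect_window_size is not None
        and config.get("window_size") not in (None, expect_window_size)
    ):
        raise CheckpointError(
            f"{path}: checkpoint window size {config.get('window_size')} "
            f"!= requested {expect_window_size}"
        )
    state = {
        name[3:]: archive[name] for name in names if name.startswith("w::")
    }
    return state, config, meta["metrics"]
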