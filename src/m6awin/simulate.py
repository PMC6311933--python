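"""Synthetic miCLIP-like data with known ground truth.

Generates random transcripts with motif instances planted at recorded
single-base positions (the A of the DRACH core), matched transcript
structures, and a truth table — enough to exercise dataset construction,
training, interpretation, and position profiling without any downloads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .encode import ALPHABET
from .io import (
    SiteRecord,
    TranscriptStructure,
    write_fasta,
    write_sites,
    write_structures,
)

DRACH_DEFAULT = "GGACU"


def consensus_to_pwm(consensus: str) -> np.ndarray:
    pwm = np.zeros((len(consensus), 4))
    for i, base in enumerate(consensus):
        pwm[i, ALPHABET.index(base)] = 1.0
    return pwm


@dataclass
class SimConfig:
    n_transcripts: int = 200
    length_min: int = 500
    length_max: int = 3000
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    motif: str = DRACH_DEFAULT  # consensus string; PWM via `motif_pwm`
    motif_pwm: np.ndarray | None = None
    site_offset: int | None = None  # offset of the methylated A in the motif
    sites_min: int = 1
    sites_max: int = 2
    plant_probability: float = 1.0  # 0 disables planting (null data)
    utr3_bias: float = 0.0  # fraction of sites forced just past utr3_start
    utr3_bias_width: float = 0.4  # span of the bias zone, as 3'UTR fraction
    utr3_fraction: float = 0.7  # utr3_start = round(fraction * length)
    last_exon_fraction: float = 0.6
    clean_background: bool = True  # scrub chance consensus matches
    spacing: str = "sparse"  # "sparse" | "free"
    min_separation: int = 1100  # sparse mode: gap + steps*stride default
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")
        if self.motif_pwm is None:
            self.motif_pwm = consensus_to_pwm(self.motif)
        self.motif_pwm = np.asarray(self.motif_pwm, dtype=float)
        if not np.allclose(self.motif_pwm.sum(axis=1), 1.0):
            raise ValueError("motif PWM rows must sum to 1")
        if len(self.motif_pwm) > self.length_min:
            raise ValueError("motif longer than the shortest transcript")
        if self.site_offset is None:
            # the methylated A: the column most committed to A
            self.site_offset = int(self.motif_pwm[:, 0].argmax())
        if self.spacing not in ("sparse", "free"):
            raise ValueError("spacing must be 'sparse' or 'free'")


@dataclass
class SimResult:
    fasta: dict[str, str]
    sites: list[SiteRecord]
    structures: dict[str, TranscriptStructure]
    truth: list[dict] = field(default_factory=list)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.fasta, outdir / "transcripts.fa")
        write_sites(self.sites, outdir / "sites.tsv")
        write_structures(self.structures, outdir / "structure.tsv")
        (outdir / "truth.json").write_text(
            json.dumps(self.truth, indent=2) + "\n"
        )


def _sample_motif(pwm: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(
        ALPHABET[rng.choice(4, p=row)] for row in pwm
    )


def _scrub_background(
    bases: np.ndarray,
    consensus: str,
    planted_spans: list[tuple[int, int]],
    rng: np.random.Generator,
) -> None:
    """Mutate chance occurrences of `consensus` outside planted spans.

    Keeps the background motif-free so labels carry clean signal; a few
    passes handle mutations that themselves create new matches.
    """
    motif_len = len(consensus)
    for _pass in range(10):
        seq = "".join(bases)
        dirty = []
        start = seq.find(consensus)
        while start != -1:
            overlaps = any(
                start < end and start + motif_len > begin
                for begin, end in planted_spans
            )
            if not overlaps:
                dirty.append(start)
            start = seq.find(consensus, start + 1)
        if not dirty:
            return
        for start in dirty:
            target = start + motif_len // 2
            current = bases[target]
            options = [b for b in ALPHABET if b != current]
            bases[target] = options[int(rng.integers(0, 3))]


def simulate(config: SimConfig) -> SimResult:
    """Generate transcripts, planted sites, structures, and truth records.

    Deterministic for a given seed.  In sparse mode no two planted loci
    on one transcript are closer than ``min_separation``, guaranteeing
    the dataset builder can always find a nearby negative window.
    """
    rng = np.random.default_rng(config.seed)
    pwm = config.motif_pwm
    motif_len = len(pwm)
    result = SimResult(fasta={}, sites=[], structures={}, truth=[])
    width = len(str(max(config.n_transcripts - 1, 0)))

    for index in range(config.n_transcripts):
        transcript_id = f"tx{index:0{width}d}"
        length = int(rng.integers(config.length_min, config.length_max + 1))
        bases = rng.choice(list(ALPHABET), size=length, p=config.background)
        utr3_start = int(round(config.utr3_fraction * length))
        last_exon_start = int(round(config.last_exon_fraction * length))
        structure = TranscriptStructure(
            transcript_id, length, last_exon_start, utr3_start
        )

        n_sites = int(rng.integers(config.sites_min, config.sites_max + 1))
        loci: list[int] = []
        min_sep = config.min_separation if config.spacing == "sparse" else motif_len
        for _ in range(n_sites):
            for _attempt in range(200):
                if config.utr3_bias > 0 and rng.random() < config.utr3_bias:
                    zone = max(
                        1, int(config.utr3_bias_width * structure.utr3_length)
                    )
                    hi = min(utr3_start + zone, length - motif_len)
                    if hi <= utr3_start:
                        continue
                    locus = int(rng.integers(utr3_start, hi + 1))
                else:
                    locus = int(rng.integers(0, length - motif_len + 1))
                if all(abs(locus - other) >= min_sep for other in loci):
                    loci.append(locus)
                    break

        planted_spans: list[tuple[int, int]] = []
        site_entries = []
        for locus in sorted(loci):
            planted = rng.random() < config.plant_probability
            if planted:
                instance = _sample_motif(pwm, rng)
                bases[locus : locus + motif_len] = list(instance)
                planted_spans.append((locus, locus + motif_len))
            else:
                instance = ""
            site_entries.append((locus, planted, instance))
        if config.clean_background:
            _scrub_background(bases, config.motif, planted_spans, rng)
        for locus, planted, instance in site_entries:
            site_position = locus + config.site_offset
            result.sites.append(
                SiteRecord(transcript_id, site_position, "sim")
            )
            result.truth.append(
                {
                    "transcript_id": transcript_id,
                    "motif_start": locus,
                    "motif_end": locus + motif_len,
                    "site_position": site_position,
                    "motif_instance": instance,
                    "planted": planted,
                }
            )
        result.fasta[transcript_id] = "".join(bases)
        result.structures[transcript_id] = structure
    return result


def degenerate_fixtures() -> dict[str, SimResult]:
    """Hand-built edge cases for the rest of the pipeline."""
    fixtures: dict[str, SimResult] = {}

    def make(name, seq, positions, last_exon_frac=0.5, utr3_frac=0.7):
        structure = TranscriptStructure(
            name,
            len(seq),
            int(last_exon_frac * len(seq)),
            int(utr3_frac * len(seq)),
        )
        return SimResult(
            fasta={name: seq},
            sites=[SiteRecord(name, p, "fixture") for p in positions],
            structures={name: structure},
            truth=[],
        )

    rng = np.random.default_rng(12345)
    background = "".join(rng.choice(list(ALPHABET), size=400))
    fixtures["terminal_site"] = make(
        "terminal_site", "A" + background[1:-1] + "A", [0, 399]
    )
    fixtures["short_transcript"] = make(
        "short_transcript", background[:60], [10]
    )
    # 5 sites spaced 30 apart: one chained cluster spanning 120 > 50
    fixtures["wide_cluster"] = make(
        "wide_cluster", background, [100, 130, 160, 190, 220]
    )
    fixtures["all_N"] = make("all_N", "N" * 200, [100])
    return fixtures


def config_to_json(config: SimConfig) -> str:
    data = asdict(config)
    data["motif_pwm"] = np.asarray(config.motif_pwm).tolist()
    return json.dumps(data, indent=2)
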