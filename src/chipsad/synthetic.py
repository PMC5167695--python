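"""Synthetic fixtures: probe layouts, piecewise-constant signal, annotation.

Every stage of the pipeline is testable without real array data.  The
generator emulates the essential geometry of bacterial two-color arrays:
probes laid end-to-end at uniform spacing (tiling) or at irregular,
skew-distributed gaps (non-tiling), carrying a piecewise-constant log2
ratio — a baseline plus a per-transcript level inside each simulated
transcript — with additive Gaussian noise on the M scale, as appropriate
for log-ratio data.  Multi-experiment mode perturbs each experiment's true
boundaries (uniform jitter) and levels (Gaussian), emulating the spread of
independently hybridized samples that the alignment stage reconciles.

Annotation fixtures build a toy GenBank genome with loci engineered to
trigger each classification rule, together with the matching signal areas
and their expected labels, so classifier tests never re-derive truth from
the code under test.  All generators are fully deterministic under the
configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO

from .annotation import OrfFeature
from .segmentation import SignalArea
from .signal_io import ProbeMeasurement, ProbeTrack


@dataclass
class SimulatedTranscript:
    replicon: str
    strand: str
    start: int
    end: int
    level_M: float
    label: str | None = None  # expected class, when annotation truth exists

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic fixtures.

    Defaults describe a realistic desk-scale bacterial tiling design: a
    20 kb replicon probed every 20 bp by end-to-end probes, log-ratio noise
    of 0.25 (typical residual scatter of normalized two-color data), zero
    baseline, and — in multi-experiment mode — boundary jitter of 20 bp
    between hybridizations.
    """

    genome_length: int = 20_000
    layout: str = "tiling"           # 'tiling' | 'nontiling'
    step: int = 20                   # tiling inter-probe start distance, bp
    probe_length: int | None = None  # default: step (tiling) or 24 (nontiling)
    mean_gap: float = 25.0           # nontiling mean inter-probe gap, bp
    gap_dispersion: float = 1.0      # gap CV; 1.0 ~ geometric-like
    noise_sd: float = 0.25           # Gaussian sd on the M scale
    baseline_M: float = 0.0
    seed: int = 0
    n_experiments: int = 1
    boundary_jitter_bp: int = 0
    level_jitter_sd: float = 0.0
    replicon: str = "synthetic_1"
    strands: tuple[str, ...] = ("+",)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    @property
    def resolved_probe_length(self) -> int:
        if self.probe_length is not None:
            return self.probe_length
        return self.step if self.layout == "tiling" else 24


# ---------------------------------------------------------------------------
# probe layout
# ---------------------------------------------------------------------------

def simulate_layout(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Probe start positions per strand, deterministic under the seed.

    Tiling: starts every ``step`` bp from position 1.  Non-tiling: gaps are
    drawn from a gamma distribution with the configured mean and coefficient
    of variation, rounded to >= 1 bp — a single-parameter skewed family that
    reproduces the irregular spacing of ORF-centric designs.
    """
    L = config.genome_length
    plen = config.resolved_probe_length
    if config.layout == "tiling":
        if config.step >= L:
            raise ValueError("step must be smaller than genome_length")
        starts = np.arange(1, L - plen + 2, config.step, dtype=np.int64)
        return {s: starts.copy() for s in config.strands}
    if config.layout == "nontiling":
        if config.mean_gap >= L:
            raise ValueError("mean_gap must be smaller than genome_length")
        rng = np.random.default_rng(config.seed)
        out = {}
        shape = 1.0 / max(config.gap_dispersion, 1e-6) ** 2
        scale = config.mean_gap / shape
        for s in config.strands:
            n_max = int(3 * L / config.mean_gap) + 10
            gaps = np.maximum(1, np.round(rng.gamma(shape, scale, n_max))).astype(np.int64)
            starts = 1 + np.concatenate([[0], np.cumsum(gaps)])
            out[s] = starts[starts <= L - plen + 1]
        return out
    raise ValueError(f"unknown layout {config.layout!r}")


# ---------------------------------------------------------------------------
# signal
# ---------------------------------------------------------------------------

def _jitter_transcripts(transcripts, config, rng) -> list[SimulatedTranscript]:
    j = config.boundary_jitter_bp
    out = []
    for t in transcripts:
        ds = int(rng.integers(-j, j + 1)) if j else 0
        de = int(rng.integers(-j, j + 1)) if j else 0
        level = t.level_M + (
            float(rng.normal(0.0, config.level_jitter_sd))
            if config.level_jitter_sd else 0.0
        )
        start = max(1, t.start + ds)
        end = min(config.genome_length, max(start, t.end + de))
        out.append(replace(t, start=start, end=end, level_M=level))
    return out


def simulate_signal(
    layout: dict[str, np.ndarray],
    transcripts: list[SimulatedTranscript],
    config: SimulationConfig,
) -> tuple[dict[str, list[ProbeTrack]], dict[str, list[SimulatedTranscript]]]:
    """Piecewise-constant probe signal plus noise for every experiment.

    A probe reports baseline + level when its midpoint lies inside a
    transcript on its strand, plus N(0, noise_sd).  Returns per-experiment
    probe tracks (one per strand) and the per-experiment ground truth (the
    jittered transcript boundaries actually used).
    """
    rng = config.rng()
    plen = config.resolved_probe_length
    tracks: dict[str, list[ProbeTrack]] = {}
    truth: dict[str, list[SimulatedTranscript]] = {}
    for e in range(config.n_experiments):
        exp = f"exp{e + 1}"
        if config.n_experiments > 1 and (config.boundary_jitter_bp or config.level_jitter_sd):
            exp_transcripts = _jitter_transcripts(transcripts, config, rng)
        else:
            exp_transcripts = list(transcripts)
        truth[exp] = exp_transcripts
        exp_tracks = []
        for strand, starts in sorted(layout.items()):
            mids = starts + plen // 2
            m = np.full(starts.shape, config.baseline_M, dtype=float)
            for t in exp_transcripts:
                if t.strand != strand or t.replicon != config.replicon:
                    continue
                inside = (mids >= t.start) & (mids <= t.end)
                m[inside] += t.level_M
            if config.noise_sd > 0:
                m = m + rng.normal(0.0, config.noise_sd, size=m.shape)
            probes = [
                ProbeMeasurement(
                    probe_id=f"{exp}_{strand}_{i:05d}",
                    replicon=config.replicon,
                    strand=strand,
                    start=int(s),
                    end=int(s) + plen - 1,
                    M=float(v),
                )
                for i, (s, v) in enumerate(zip(starts, m))
            ]
            exp_tracks.append(
                ProbeTrack(exp, config.replicon, strand, probes)
            )
        tracks[exp] = exp_tracks
    return tracks, truth


def thin_track(track: ProbeTrack, fraction: float, seed: int = 0) -> ProbeTrack:
    """Randomly keep a fraction of probes — turns a tiled track non-tiled."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n = len(track)
    keep = np.sort(rng.choice(n, size=max(2, int(round(fraction * n))), replace=False))
    return ProbeTrack(
        track.experiment_id, track.replicon, track.strand,
        [track.probes[i] for i in keep],
    )


def random_transcripts(
    config: SimulationConfig,
    n: int,
    min_probes: int = 12,
    max_probes: int = 25,
    level_range: tuple[float, float] = (1.0, 2.5),
    strand: str = "+",
    rng: np.random.Generator | None = None,
) -> list[SimulatedTranscript]:
    """Non-overlapping transcripts on the probe grid with |level| in range.

    The genome is split into ``n`` equal slots; each slot holds one
    transcript of random grid-aligned length, with a buffer of at least
    three probe steps to the slot edges so neighbouring transcripts stay
    separable.  Level signs are random.
    """
    if rng is None:
        rng = config.rng()
    step = config.step
    slot = config.genome_length // n
    if slot < (min_probes + 6) * step:
        raise ValueError("genome too short for the requested transcripts")
    out = []
    for i in range(n):
        n_probes = int(rng.integers(min_probes, max_probes + 1))
        n_probes = min(n_probes, (slot - 7 * step) // step)  # keep inside the slot
        length = n_probes * step
        lo = i * slot + 3 * step
        hi = (i + 1) * slot - 3 * step - length
        start_grid = int(rng.integers(lo // step, max(lo // step + 1, hi // step)))
        start = start_grid * step + 1
        level = float(rng.uniform(*level_range)) * (1 if rng.random() < 0.5 else -1)
        out.append(
            SimulatedTranscript(config.replicon, strand, start, start + length - 1, level)
        )
    return out


# ---------------------------------------------------------------------------
# annotation fixtures
# ---------------------------------------------------------------------------

@dataclass
class AnnotationFixture:
    """A toy genome: ORFs, signal areas, and their expected class labels."""

    replicon: str
    genome_length: int
    orfs: list[OrfFeature]
    sas: list[SignalArea]
    expected_labels: list[str]
    record: SeqRecord = field(repr=False, default=None)

    def write_genbank(self, path) -> None:
        SeqIO.write([self.record], str(path), "genbank")


def _mk_sas(replicon, strand, start, end, m=2.0) -> SignalArea:
    return SignalArea(
        experiment_id="truth", replicon=replicon, strand=strand,
        start=start, end=end, pseudomedian_M=m, n_probes=max(1, (end - start) // 20),
    )


def _one_per_class_loci(replicon: str):
    """Seven engineered loci, one per classification outcome.

    Returns (orfs, sas, labels); loci are spaced >= 2 kb apart so no rule
    sees a neighbour.
    """
    orfs = [
        # operon pair (co-oriented, + strand)
        OrfFeature("op_a", replicon, "+", 1000, 1600),
        OrfFeature("op_b", replicon, "+", 1700, 2300),
        # convergent pair with a 20 bp gap
        OrfFeature("ou_a", replicon, "+", 5000, 5600),
        OrfFeature("ou_b", replicon, "-", 5621, 6200),
        # plain sense ORF
        OrfFeature("orf_a", replicon, "+", 9000, 9900),
        # ORF with a long 5' extension
        OrfFeature("utr_a", replicon, "+", 13000, 13900),
        # ORF hit only in antisense
        OrfFeature("as_a", replicon, "-", 17000, 17900),
    ]
    sas = [
        _mk_sas(replicon, "+", 950, 2350),      # covers both operon ORFs fully
        _mk_sas(replicon, "+", 5300, 5900),     # spans the convergent gap
        _mk_sas(replicon, "+", 8990, 9910),     # single ORF, <=30 bp overhangs
        _mk_sas(replicon, "+", 12700, 13920),   # 300 bp 5' extension
        _mk_sas(replicon, "+", 17100, 17800),   # inside as_a, wrong strand
        _mk_sas(replicon, "+", 21000, 21500),   # short orphan (501 bp)
        _mk_sas(replicon, "+", 24000, 25200),   # long orphan (1201 bp)
    ]
    labels = [
        "operon", "overlapping_utr", "orf", "utr5",
        "antisense", "intergenic", "intergenic_long",
    ]
    return orfs, sas, labels


def _random_scenario_loci(replicon: str, rng: np.random.Generator):
    """Randomized per-locus templates whose labels are known by construction.

    Each locus draws one rule template with randomized sizes, gaps and
    offsets kept inside rule-safe margins, then the loci are laid out left
    to right with 2 kb spacers.
    """
    orfs: list[OrfFeature] = []
    sas: list[SignalArea] = []
    labels: list[str] = []
    cursor = 1000
    n_loci = int(rng.integers(5, 10))
    for li in range(n_loci):
        template = str(rng.choice([
            "operon", "overlapping_utr", "orf", "utr5", "utr3",
            "antisense", "intergenic", "intergenic_long",
        ]))
        strand = "+" if rng.random() < 0.5 else "-"
        olen = int(rng.integers(400, 1200))
        tag = f"L{li}"
        if template == "operon":
            gap = int(rng.integers(40, 200))
            o1 = OrfFeature(f"{tag}a", replicon, strand, cursor, cursor + olen - 1)
            o2 = OrfFeature(
                f"{tag}b", replicon, strand, o1.end + gap + 1, o1.end + gap + olen
            )
            orfs += [o1, o2]
            sas.append(_mk_sas(replicon, strand, o1.start - 10, o2.end + 10))
            cursor = o2.end
        elif template == "overlapping_utr":
            gap = int(rng.integers(0, 30))
            o1 = OrfFeature(f"{tag}a", replicon, strand, cursor, cursor + olen - 1)
            o2 = OrfFeature(
                f"{tag}b", replicon, "-" if strand == "+" else "+",
                o1.end + gap + 1, o1.end + gap + olen,
            )
            orfs += [o1, o2]
            # span the junction; keep each overlap under 30% of either ORF
            # so the operon/ORF rules cannot fire first
            reach = int(min(olen * 0.25, rng.integers(60, 140)))
            sas.append(_mk_sas(replicon, strand, o1.end - reach, o2.start + reach))
            cursor = o2.end
        elif template == "orf":
            o = OrfFeature(tag, replicon, strand, cursor, cursor + olen - 1)
            orfs.append(o)
            pad_l = int(rng.integers(0, 31))
            pad_r = int(rng.integers(0, 31))
            sas.append(_mk_sas(replicon, strand, o.start - pad_l, o.end + pad_r))
            cursor = o.end
        elif template in ("utr5", "utr3"):
            o = OrfFeature(tag, replicon, strand, cursor, cursor + olen - 1)
            orfs.append(o)
            ext = int(rng.integers(101, 400))
            upstream_low = (strand == "+") == (template == "utr5")
            if upstream_low:
                sas.append(_mk_sas(replicon, strand, o.start - ext, o.end + int(rng.integers(0, 31))))
            else:
                sas.append(_mk_sas(replicon, strand, o.start - int(rng.integers(0, 31)), o.end + ext))
            cursor = o.end + ext
        elif template == "antisense":
            o = OrfFeature(tag, replicon, "-" if strand == "+" else "+", cursor, cursor + olen - 1)
            orfs.append(o)
            inset = int(rng.integers(0, olen // 4))
            sas.append(_mk_sas(replicon, strand, o.start + inset, o.end - inset))
            cursor = o.end
        elif template == "intergenic":
            length = int(rng.integers(100, 799))
            sas.append(_mk_sas(replicon, strand, cursor, cursor + length - 1))
            cursor = cursor + length
        else:  # intergenic_long
            length = int(rng.integers(800, 2000))
            sas.append(_mk_sas(replicon, strand, cursor, cursor + length - 1))
            cursor = cursor + length
        labels.append(template)
        cursor += 2000
    return orfs, sas, labels, cursor + 1000


def simulate_annotation(
    config: SimulationConfig, scenario: str = "one_per_class", out_path=None
) -> AnnotationFixture:
    """Toy GenBank annotation plus signal areas with known class labels.

    ``one_per_class`` engineers exactly one locus per classification
    outcome; ``random`` draws a randomized set of rule templates under the
    config seed.  When ``out_path`` is given the GenBank file is written
    there as well.
    """
    replicon = config.replicon
    if scenario == "one_per_class":
        orfs, sas, labels = _one_per_class_loci(replicon)
        length = 26_000
    elif scenario == "random":
        orfs, sas, labels, length = _random_scenario_loci(replicon, config.rng())
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    record = SeqRecord(
        Seq("A" * length),
        id=replicon,
        name=replicon[:16],
        description="synthetic annotation fixture",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    for o in orfs:
        record.features.append(
            SeqFeature(
                FeatureLocation(o.start - 1, o.end, strand=1 if o.strand == "+" else -1),
                type="CDS",
                qualifiers={"locus_tag": [o.locus_tag], "product": ["synthetic protein"]},
            )
        )
    fixture = AnnotationFixture(
        replicon=replicon, genome_length=length, orfs=orfs,
        sas=sas, expected_labels=labels, record=record,
    )
    if out_path is not None:
        fixture.write_genbank(out_path)
    return fixture
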