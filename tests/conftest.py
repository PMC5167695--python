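"""Shared fixtures: small deterministic tracks and synthetic genomes."""

import numpy as np
import pytest

from chipsad import (
    ProbeMeasurement,
    ProbeTrack,
    SimulatedTranscript,
    SimulationConfig,
    simulate_layout,
    simulate_signal,
)

REPLICON = "synthetic_1"

# the noiseless three-transcript tiling genome used across segmentation tests
THREE_TRANSCRIPTS = [
    (1001, 2000),
    (2601, 3600),
    (4201, 5200),
]


def make_track(m_values, start0=1, step=10, probe_len=10, strand="+",
               experiment="exp1"):
    """A uniform tiled track carrying the given M values."""
    probes = [
        ProbeMeasurement(
            probe_id=f"p{i}", replicon=REPLICON, strand=strand,
            start=start0 + i * step, end=start0 + i * step + probe_len - 1,
            M=float(m),
        )
        for i, m in enumerate(m_values)
    ]
    return ProbeTrack(experiment, REPLICON, strand, probes)


def jaccard(a, b):
    """Interval Jaccard on 1-based inclusive (start, end) pairs."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union


@pytest.fixture
def three_transcript_fixture():
    """Noiseless tiled genome with three |dM|=2 transcripts; returns
    (track, transcripts, config)."""
    cfg = SimulationConfig(
        genome_length=6000, step=10, probe_length=10, noise_sd=0.0, seed=1
    )
    transcripts = [
        SimulatedTranscript(REPLICON, "+", s, e, 2.0) for s, e in THREE_TRANSCRIPTS
    ]
    tracks, _ = simulate_signal(simulate_layout(cfg), transcripts, cfg)
    return tracks["exp1"][0], transcripts, cfg
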