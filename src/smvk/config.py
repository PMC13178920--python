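"""Run configuration and reproducible random-number streams.

All randomness in the pipeline flows from a single integer seed through
named sub-streams, one per stage, so that re-running any stage in
isolation reproduces its draws bit-for-bit and no two stages ever share
a stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RunConfig", "rng_stream"]


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """Return the named child generator of the root seed.

    The stream is keyed by a CRC32 of the stream name, so distinct names
    yield statistically independent generators and the mapping is stable
    across sessions and platforms.
    """
    if not name:
        raise ValueError("stream name must be non-empty")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


@dataclass
class RunConfig:
    """Pipeline-wide defaults.

    Thresholds mirror the published analysis settings: 5 ppm metabolite
    annotation tolerance, top-30 / pct.1 > 0.8 panel pre-filter, module
    scoring with 24 bins x 100 controls, SSC at (r=1, k=15, s=3),
    DEG cutoffs |log2FC| > 1 at adjusted p < 0.05, rolling-ball radius
    15 px, 3 um cytoplasmic expansion and a 25-200 um^2 nuclear filter.
    """

    seed: int = 0
    out_dir: Path = field(default_factory=lambda: Path("results"))

    # metabolite annotation
    ppm_tol: float = 5.0

    # marker panel selection
    panel_top_n: int = 30
    panel_pct1_min: float = 0.8

    # module (signature) scoring
    score_nbins: int = 24
    score_nctrl: int = 100

    # differential thresholds (genes and metabolites)
    lfc_min: float = 1.0
    q_max: float = 0.05

    # spatial shrunken centroids
    ssc_r: int = 1
    ssc_k: int = 15
    ssc_s: float = 3.0

    # MIF quantification
    rolling_ball_radius: int = 15
    expansion_um: float = 3.0
    area_min_um2: float = 25.0
    area_max_um2: float = 200.0

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("ppm_tol", "panel_pct1_min", "lfc_min", "q_max",
                     "ssc_s", "expansion_um", "area_min_um2", "area_max_um2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def stream(self, name: str) -> np.random.Generator:
        return rng_stream(self.seed, name)
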