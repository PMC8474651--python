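"""Deterministic end-to-end fixtures: canonical neurons with recorded seeds.

Each fixture spec pins every random ingredient (target information, mean
rate, behavior, spikes, noise) to a named seed, so regenerating a fixture is
byte-identical — the basis for regression tests and the worked examples.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import behavior as bhv
from . import fluorescence as fluo
from . import ratemaps as rm
from . import spiketrain as spk

__all__ = ["FixtureSpec", "FixtureBundle", "CANONICAL_SPECS", "make_fixture", "write_fixture"]


@dataclass
class FixtureSpec:
    name: str
    seed: int
    target_info_ap: float      # bits/AP
    mean_rate: float = 1.0     # Hz
    session_minutes: float = 10.0
    indicator: str = "gCaMP6f"
    noise_sd: float = fluo.NOISE_SD
    behavior: dict = field(default_factory=dict)


# Canonical low- and high-information neurons used throughout the examples.
CANONICAL_SPECS = {
    "lo_info": FixtureSpec("lo_info", seed=11, target_info_ap=0.04, mean_rate=1.0),
    "hi_info": FixtureSpec("hi_info", seed=12, target_info_ap=2.0, mean_rate=1.0),
}


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    ratemap: rm.RateMap
    trace: bhv.BehaviorTrace
    train: spk.SpikeTrain
    frames: spk.FrameSeries   # AP counts
    dff: spk.FrameSeries      # noisy dF/F


def make_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Generate the full bundle for a spec; pure function of the spec."""
    ss = np.random.SeedSequence(spec.seed)
    ss_map, ss_beh, ss_spk, ss_noise = ss.spawn(4)
    map_ = rm.optimize_ratemap(spec.target_info_ap, seed=np.random.default_rng(ss_map))
    map_.mean_rate = spec.mean_rate
    map_.seed = spec.seed
    trace = bhv.synth_behavior(
        spec.session_minutes * 60.0, seed=np.random.default_rng(ss_beh), **spec.behavior
    )
    cif = spk.build_cif(map_, trace)
    train = spk.generate_spikes(cif, seed=np.random.default_rng(ss_spk))
    frames = spk.bin_to_frames(train)
    kernel = fluo.get_kernel(spec.indicator)
    dff = fluo.synth_fluorescence(
        train, kernel, noise_sd=spec.noise_sd, seed=np.random.default_rng(ss_noise)
    )
    return FixtureBundle(spec, map_, trace, train, frames, dff)


def write_fixture(bundle: FixtureBundle, directory) -> dict:
    """Write the bundle as CSVs plus a manifest with a content checksum."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rm.save_library([bundle.ratemap], d / "ratemap.csv")
    bhv.save_behavior(bundle.trace, d / "behavior.txt")
    spk.save_spike_times(bundle.train, d / "spikes.txt")
    fluo.save_dff(bundle.dff, d / "dff.csv")
    h = hashlib.sha256()
    for name in ("ratemap.csv", "behavior.txt", "spikes.txt", "dff.csv"):
        h.update((d / name).read_bytes())
    manifest = {
        "spec": asdict(bundle.spec),
        "achieved_info_ap": bundle.ratemap.achieved_info_ap,
        "n_spikes": bundle.train.n_spikes,
        "checksum": h.hexdigest(),
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
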