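"""Shared fixtures: generator-calibrated thresholds and the full
synapse-recovery experiment (built once per session; they are the slowest
pieces of the suite)."""

from __future__ import annotations

import sys
import warnings
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from dendron import (CalibrationResult, ExmGeneratorParams,
                     calibrate_thresholds, choose_orientation, detect_puncta,
                     extract_profile, find_appositions, generate_exm_volume,
                     quantify_volume)

E = 4.2


def collect_synapse_profiles(seeds, synapse_rate=4.0, noise_sd=0.02):
    """Side-on and face-on profiles of true synapses from decoy-free
    generator volumes, together with the matched true diameters."""
    side, face = [], []
    side_d, face_d = [], []
    for seed in seeds:
        p = ExmGeneratorParams(seed=seed, noise_sd=noise_sd,
                               synapse_rate=synapse_rate, decoy_rate=0.0)
        vol, line, truth = generate_exm_volume(p)
        apps = find_appositions(detect_puncta(vol), line,
                                p.dendrite_radius, E)
        for a in apps:
            choose_orientation(a)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                a.profile = extract_profile(a, vol)
            # nearest truth punctum for the matched diameter
            dists = [np.linalg.norm(np.asarray(r["centroid_um_post"])
                                    - a.punctum.centroid)
                     for r in truth.punctum_records]
            d_true = truth.punctum_records[int(np.argmin(dists))][
                "diameter_um_pre"]
            if a.orientation == "side_on":
                side.append(a.profile)
                side_d.append(d_true)
            else:
                face.append(a.profile)
                face_d.append(d_true)
    return side, face, side_d, face_d


@pytest.fixture(scope="session")
def exm_calibration():
    """Thresholds calibrated on generator ground-truth synapses."""
    side, face, side_d, face_d = [], [], [], []
    seed = 1000
    while len(side) < 15 or len(face) < 10:
        s, f, sd, fd = collect_synapse_profiles([seed])
        side += s
        face += f
        side_d += sd
        face_d += fd
        seed += 1
        assert seed < 1040, "calibration set failed to fill"
    cal = calibrate_thresholds(side, face, E)
    cal.overlaps["side_true_diameters"] = side_d
    cal.overlaps["face_true_diameters"] = face_d
    return cal


def run_recovery(cal: CalibrationResult, seeds, noise_sd=0.02,
                 decoy_gap=1.0):
    """Run the full pipeline against generator truth over several seeds.

    A truth punctum counts as called when some called-synapse detection
    lies within the sum of the two radii (post-expansion) of its centroid,
    i.e. the detected and true boutons touch.
    """
    tp = fn = tn = fp = 0
    for s in seeds:
        p = ExmGeneratorParams(seed=s, noise_sd=noise_sd,
                               decoy_gap=decoy_gap)
        vol, line, truth = generate_exm_volume(p)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, rows = quantify_volume(vol, line, cal,
                                      dendrite_radius=p.dendrite_radius)
        for rec in truth.punctum_records:
            c = np.asarray(rec["centroid_um_post"])
            called = any(
                r["is_synapse"]
                and np.linalg.norm(np.asarray(r["centroid_um_post"]) - c)
                <= E * (rec["diameter_um_pre"] + r["diameter_um_pre"]) / 2
                for r in rows)
            if rec["label"] == "synapse":
                tp += called
                fn += not called
            else:
                fp += called
                tn += not called
    sens = tp / max(tp + fn, 1)
    spec = tn / max(tn + fp, 1)
    return {"sensitivity": sens, "specificity": spec,
            "n_synapses": tp + fn, "n_decoys": tn + fp}


@pytest.fixture(scope="session")
def exm_recovery(exm_calibration):
    return run_recovery(exm_calibration, seeds=range(20))
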