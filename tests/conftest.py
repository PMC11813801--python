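import numpy as np
import pytest

from motifpairs.calibration import CalibrationConfig, base_composition
from motifpairs.motif_models import matrix_from_consensus
from motifpairs.pair_analysis import CalibratedMotif, calibrate_motif
from motifpairs.recognition import DatasetPair
from motifpairs.synthetic_data import (
    ImplantRegime,
    gen_background,
    gen_negatives,
    implant,
)

MOTIF_A = "ACCGTTGA"
MOTIF_B = "TGCATCGT"
MOTIF_C = "GGATCTTC"


@pytest.fixture(scope="session")
def promoters():
    """Small reference set for ERR calibration (60 x 500 bp, GC 0.5)."""
    return gen_background(60, 500, 0.5, seed=11, label="promoter", prefix="prom")


@pytest.fixture(scope="session")
def calibrated(promoters):
    """Three calibrated consensus motifs sharing the promoter background."""
    bg = base_composition(promoters)
    cfg = CalibrationConfig()
    return {
        name: calibrate_motif(
            matrix_from_consensus(cons, name), promoters, background=bg, config=cfg
        )
        for name, cons in [("A", MOTIF_A), ("B", MOTIF_B), ("C", MOTIF_C)]
    }


@pytest.fixture(scope="session")
def exclusive_data():
    """Peaks with A/B implanted mutually exclusively, plus matched negatives."""
    bg = gen_background(80, 120, 0.5, seed=12, label="positive", prefix="peak")
    peaks, truth = implant(
        bg, ImplantRegime("exclusive", 0.5, 0.5, MOTIF_A, MOTIF_B, seed=13)
    )
    negatives = gen_negatives(peaks, per_peak=5, seed=14)
    return DatasetPair(positive=peaks, negative=negatives), truth
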