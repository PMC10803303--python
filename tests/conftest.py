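"""Shared fixtures.

The expensive end-to-end artefacts (trained segmenter, 200-case cohort with
feature pyramids, classifier ablation) are built once per session and shared
between the unit tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from mlnet.classification import ClassifierConfig, predict_scores, run_ablation
from mlnet.evalstats import dice
from mlnet.orchestrate import SplitPlan, centre_split
from mlnet.phantom import CentreProfile, PhantomSpec, default_centres, generate_case, generate_cohort
from mlnet.segmentation import UNetConfig, extract_features, predict_mask, train_segmenter

SMALL_SPEC = PhantomSpec(
    grid_shape=(16, 16, 16),
    tumour_radius_range=(2.8, 3.8),
    emvi_protrusions=(2, 2.5, 1.1),
)


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    return SMALL_SPEC


@pytest.fixture(scope="session")
def quiet_centre() -> CentreProfile:
    return CentreProfile("C1", gain=1.0, bias_amplitude=0.02, noise_sigma=0.04)


@pytest.fixture(scope="session")
def small_case(quiet_centre):
    return generate_case(SMALL_SPEC, quiet_centre, emvi=1, cr=0, seed=99)


@pytest.fixture(scope="session")
def small_cohort(quiet_centre):
    """24 easy 16^3 phantoms from one centre (fast unit-test fodder)."""
    return [
        generate_case(SMALL_SPEC, quiet_centre, s % 2, (s // 2) % 2, seed=500 + s)
        for s in range(24)
    ]


@pytest.fixture(scope="session")
def pipeline200():
    """The end-to-end artefact behind the segmentation-replication and
    feature-injection acceptance criteria: a 200-case multi-centre cohort,
    a segmenter trained on train-centre cases, held-out Dice, feature
    pyramids for every case and the 6-variant ablation on the EMVI task.
    """
    centres = default_centres(9, seed=11)
    cohort = generate_cohort(200, centres, p_emvi=0.60, p_cr=0.28, seed=123)
    plan = SplitPlan({"C1", "C2", "C3", "C4"}, {"C5", "C6"}, {"C7", "C8", "C9"})
    train, internal, external = centre_split(cohort, plan)

    seg_cfg = UNetConfig(seed=7)
    segmenter, seg_log = train_segmenter(
        train[:40], seg_cfg, epochs=5, val_cases=internal[:8], lr=3e-3
    )
    heldout_dice = [
        dice(predict_mask(segmenter, c.image), c.mask) for c in external[:12]
    ]
    pyramids = {c.patient_id: extract_features(segmenter, c.image) for c in cohort}

    base = ClassifierConfig(
        variant="mlnet", learning_rate=1e-3, batch_size=4, patience=10,
        max_epochs=16, sam_rho=0.05, seed=21,
    )
    # the four variants the acceptance criteria compare; the full 6-variant
    # enumeration contract is exercised at small scale in test_orchestrate
    ablation = run_ablation(
        (train, internal, external), pyramids, base, task="emvi",
        variants=("mlnet", "plain_resnet10", "stage1", "stage4"),
    )

    return {
        "cohort": cohort,
        "splits": (train, internal, external),
        "segmenter": segmenter,
        "seg_log": seg_log,
        "heldout_dice": np.asarray(heldout_dice),
        "pyramids": pyramids,
        "base_config": base,
        "ablation": ablation,
    }
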