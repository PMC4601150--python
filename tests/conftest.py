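
import pytest
from hypothesis import HealthCheck, settings

from stenoquant import RunConfig, run_pipeline
from stenoquant.thresholds import ThresholdSet

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom_thresholds() -> ThresholdSet:
    """Noise-free phantom band: lumen 300, background 60 -> LT 140."""
    return ThresholdSet(aorta_value=300.0, background_value=60.0, lt=140.0, ut=None)


@pytest.fixture(scope="session")
def recovery_runs(tmp_path_factory):
    """Full pipeline runs on the six noise-free recovery phantoms
    (CTA/MRA x true Dred 30/50/70 %), shared across tests."""
    runs = {}
    for modality in ("CTA", "MRA"):
        for dred in (30.0, 50.0, 70.0):
            out = tmp_path_factory.mktemp(f"run_{modality}_{int(dred)}")
            cfg = RunConfig(
                modality=modality, dred_pct=dred, seed=1, out_dir=str(out)
            )
            runs[(modality, dred)] = run_pipeline(cfg)
    return runs
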