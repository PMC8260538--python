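"""Shared fixtures.

The expensive session fixtures train real (tiny-preset) models on synthetic
scenes; they are shared by the acceptance tests so each training run happens
exactly once per session.
"""

from __future__ import annotations

import pytest

from surgseg.synthetic import SynthConfig, generate_scenes
from surgseg.network import ModelConfig
from surgseg.pipeline import tiny_train_config, train, presence_prior
from surgseg.evaluation import evaluate_model


@pytest.fixture(scope="session")
def sample_scenes():
    """Ten deterministic scenes with at least one instrument each."""
    return generate_scenes(SynthConfig(n_instruments=(1, 4)), 10, 123)


@pytest.fixture(scope="session")
def thousand_scenes():
    """1,000 seeded scenes under the default generator conditions."""
    return generate_scenes(SynthConfig(), 1000, 77)


@pytest.fixture(scope="session")
def trained_full():
    """One tiny-preset model trained under the reference study conditions:
    200 synthetic 64x80 scenes, 30 epochs, fixed seed; scored on 50 held-out
    scenes."""
    cfg = SynthConfig()
    train_scenes = generate_scenes(cfg, 200, 1000)
    eval_scenes = generate_scenes(cfg, 50, 2000)
    res = train(ModelConfig(preset="tiny", init_seed=1),
                tiny_train_config(seed=1), train_scenes)
    report = evaluate_model(res.model, eval_scenes)
    return {"result": res, "report": report, "eval_scenes": eval_scenes,
            "train_scenes": train_scenes}


@pytest.fixture(scope="session")
def directional_arms(trained_full):
    """Equal-budget arms for the directional comparisons: the reference
    model doubles as the proposed / no-prior arm, and the semantic-type
    ablation and presence-prior arms train on the same scenes with the
    same seed and schedule."""
    train_scenes = trained_full["train_scenes"]
    eval_scenes = trained_full["eval_scenes"]
    out = {"proposed": trained_full["report"]}
    arms = {
        "semantic_type": dict(variant="semantic_type", use_prior=False),
        "prior": dict(variant="proposed", use_prior=True),
    }
    for name, kw in arms.items():
        mc = ModelConfig(preset="tiny", init_seed=1, **kw)
        res = train(mc, tiny_train_config(seed=1), train_scenes)
        prior_fn = (lambda s: presence_prior(s, mc.n_classes)) \
            if kw["use_prior"] else None
        out[name] = evaluate_model(res.model, eval_scenes, prior_fn=prior_fn)
    return out
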