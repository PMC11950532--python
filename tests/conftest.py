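"""Shared fixtures: a small phantom dataset and a trained desk-scale model.

Everything is generated programmatically at test time; the heavier
fixtures are session-scoped so training happens once.
"""

from __future__ import annotations

import numpy as np
import pytest

from xbrainage.models import (NetSpec, TrainConfig, select_best_checkpoint,
                              train_cae, train_regressor, transfer_encoder)
from xbrainage.phantom import (AtlasSpec, EffectModel, build_atlas,
                               render_subject, sample_cohort)


@pytest.fixture(scope="session")
def small_phantom():
    """16^3 grid, 6 regions, one channel, 80 subjects with strong age signal."""
    atlas, region_table = build_atlas(AtlasSpec((16, 16, 16), 6, seed=11))
    effects = EffectModel.default(n_regions=6, n_disease=2, n_channels=1,
                                  seed=11)
    cohort = sample_cohort(80, 0.0, seed=12)
    volumes = np.stack([render_subject(row, atlas, effects, seed=13)
                        for _, row in cohort.iterrows()])
    return {"atlas": atlas, "region_table": region_table, "effects": effects,
            "cohort": cohort, "volumes": volumes,
            "ages": cohort["age"].to_numpy()}


@pytest.fixture(scope="session")
def net_spec_small():
    return NetSpec(input_shape=(16, 16, 16), in_channels=1,
                   encoder_widths=(4, 8, 16), latent_dim=32, head_widths=(16,))


@pytest.fixture(scope="session")
def trained_small_model(small_phantom, net_spec_small):
    """CAE-pretrained, transfer-learned age regressor on the small phantom."""
    vols, ages = small_phantom["volumes"], small_phantom["ages"]
    cae_cfg = TrainConfig(epochs=6, batch_size=8, selection_window=4, seed=21)
    store, _ = train_cae(vols[:56], vols[56:64], net_spec_small, cae_cfg)
    cae_state, _ = select_best_checkpoint(store, 4)
    model = transfer_encoder(cae_state, net_spec_small, seed=22)
    reg_cfg = TrainConfig(epochs=30, batch_size=8, learning_rate=1e-2,
                          selection_window=30, seed=23)
    reg_store, _ = train_regressor(model, vols[:56], ages[:56],
                                   vols[64:], ages[64:],
                                   net_spec_small, reg_cfg)
    best, epoch = select_best_checkpoint(reg_store, 30)
    model.load_state_dict(best)
    return {"model": model, "spec": net_spec_small, "cae_state": cae_state,
            "reg_store": reg_store, "chosen_epoch": epoch,
            **small_phantom}
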