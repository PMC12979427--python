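"""Frozen desk-scale experiment profiles.

The full-scale defaults (8 heads of width 72, 3 layers, learning rate 4e-4,
1000 epochs, 10 folds) assume a large graph and hours of training. For
laptop-scale studies on the default synthetic world we fix one smaller
profile here — chosen once, up front — so that scripts and tests run the
same configuration: a 64-wide encoder (4 heads of 16), two layers, a higher
learning rate matched to the smaller problem, and 3-fold cross-validation.

The permuted-label control uses a shorter budget because there is no signal
to fit; its purpose is only to show chance-level held-out ranking.
"""

from __future__ import annotations

from .network import ModelConfig
from .training import TrainConfig

#: folds used by desk-scale cross-validation
DESK_FOLDS = 3

DESK_MODEL = ModelConfig(heads=4, head_dim=16, layers=2, dropout=0.18,
                         gate_hidden=32, hci_hidden=256)

DESK_TRAIN = TrainConfig(learning_rate=3e-3, weight_decay=1e-5,
                         batch_size=512, max_epochs=120,
                         early_stop_patience=30, scheduler_patience=10,
                         seed=42)

PERMUTED_TRAIN = TrainConfig(learning_rate=3e-3, weight_decay=1e-5,
                             batch_size=512, max_epochs=40,
                             early_stop_patience=15, scheduler_patience=10,
                             seed=42)
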