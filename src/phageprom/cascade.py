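"""Two-layer decision cascade: promoter gate, then phage-vs-host call.

Layer 1 scores each query as promoter vs non-promoter; only sequences passing
the layer-1 threshold are forwarded to layer 2, which scores them as phage vs
host promoter. ``p_phage`` is the probability of the *phage* class (the label
mapping is stated explicitly because conventions differ: in the benchmark the
phage promoters are the layer-2 "negative"/minority class and host promoters
the "positive"/majority class).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cnn_model import CNNConfig, PromoterCNN
from .encoders import encode_dataset
from .sequence_io import DataError, SequenceDataset

CALLS = ("non_promoter", "phage_promoter", "host_promoter")


@dataclass
class CascadeResult:
    """Per-sequence three-way call with both layer probabilities.

    ``p_phage`` is present iff ``p_promoter`` passed the layer-1 threshold.
    """

    id: str
    p_promoter: float
    p_phage: float | None
    call: str


@dataclass
class CascadeModel:
    layer1: PromoterCNN
    layer2: PromoterCNN
    threshold: float = 0.5
    threshold2: float = 0.5
    encoding: str = "onehot"

    def __post_init__(self) -> None:
        if self.layer1.input_shape[0] != self.layer2.input_shape[0]:
            raise DataError("cascade layers must share the input length")

    def save(self, path_layer1, path_layer2) -> None:
        self.layer1.save(path_layer1)
        self.layer2.save(path_layer2)


def predict_cascade(model: CascadeModel, ds: SequenceDataset) -> list[CascadeResult]:
    """Run the two-layer flow; layer 2 only sees layer-1 positives."""
    if len(ds) == 0:
        return []
    X = encode_dataset(ds.sequences(), model.encoding)
    p1 = model.layer1.predict_proba(X)
    gated = np.where(p1 >= model.threshold)[0]
    p2 = np.full(len(ds), np.nan)
    if gated.size:
        p2[gated] = model.layer2.predict_proba(X[gated])
    results = []
    for i, rec in enumerate(ds):
        if i in set(gated.tolist()):
            call = (
                "phage_promoter" if p2[i] >= model.threshold2 else "host_promoter"
            )
            results.append(CascadeResult(rec.id, float(p1[i]), float(p2[i]), call))
        else:
            results.append(CascadeResult(rec.id, float(p1[i]), None, "non_promoter"))
    return results


def train_cascade(
    layer1_ds: SequenceDataset,
    layer2_ds: SequenceDataset,
    cfg: CNNConfig | None = None,
    cfg2: CNNConfig | None = None,
    encoding: str = "onehot",
) -> CascadeModel:
    """Train the two CNNs independently and package them with one threshold.

    ``layer1_ds`` must be labeled promoter / non_promoter and ``layer2_ds``
    phage / host; layer-2 training is unweighted by default, mirroring the
    benchmark's 111-vs-382 class imbalance.
    """
    cfg = cfg or CNNConfig()
    cfg2 = cfg2 or cfg
    for ds, allowed, which in (
        (layer1_ds, {"promoter", "non_promoter"}, "layer1"),
        (layer2_ds, {"phage", "host"}, "layer2"),
    ):
        got = set(ds.class_counts)
        if not got or not got <= allowed:
            raise DataError(
                f"{which} dataset labels {sorted(got)} not within {sorted(allowed)}"
            )
    X1 = encode_dataset(layer1_ds.sequences(), encoding)
    y1 = np.array([1 if l == "promoter" else 0 for l in layer1_ds.labels()])
    X2 = encode_dataset(layer2_ds.sequences(), encoding)
    y2 = np.array([1 if l == "phage" else 0 for l in layer2_ds.labels()])
    layer1 = PromoterCNN(cfg, X1.shape[1:]).fit(X1, y1)
    layer2 = PromoterCNN(cfg2, X2.shape[1:]).fit(X2, y2)
    return CascadeModel(layer1=layer1, layer2=layer2, encoding=encoding)


def call_to_label(call: str) -> str | None:
    """Map a cascade call to the dataset label vocabulary."""
    return {"phage_promoter": "phage", "host_promoter": "host",
            "non_promoter": "non_promoter"}[call]
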