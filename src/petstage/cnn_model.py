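"""Multi-task convolutional classifier for PET/CT uptake regions.

A shared convolutional trunk processes the 26-channel 64x64 MPR stack
(13 planes x 2 modalities); two fully connected heads produce

* ``p_suspicious`` — sigmoid probability that the region is suspicious for
  prostate cancer, and
* ``location_probs`` — softmax distribution over anatomical location
  classes.

In the dual-tracer variant a single binary input encoding the radiotracer
(0 = PSMA-ligand, 1 = FDG) is concatenated to the input of the first fully
connected layer of the *suspicious* head only; the location head never sees
the tracer bit, so location predictions are tracer-invariant by
construction and the gradient of the location loss with respect to the
tracer-bit weights is identically zero.

Exact filter counts are configuration, not contract: the architectural
claims this module fixes are the multi-task split and the tracer-bit
placement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from petstage import nn
from petstage.errors import ConfigurationError
from petstage.mpr_features import MprStack

TRACER_BIT = {"PSMA": 0.0, "FDG": 1.0}


@dataclass
class ModelConfig:
    n_location_classes: int
    conv_blocks: int = 4
    base_filters: int = 16
    max_filters: int = 128
    fc_width: int = 128
    dual_tracer: bool = False
    dropout: float = 0.0
    input_channels: int = 26
    input_size: int = 64
    pool_first: bool = False  # fixed 2x2 max pool before the trunk

    def __post_init__(self) -> None:
        if self.n_location_classes < 2:
            raise ConfigurationError("n_location_classes must be >= 2")
        for name in ("conv_blocks", "base_filters", "fc_width"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        eff = self.input_size // (2 if self.pool_first else 1)
        if eff % (2**self.conv_blocks) != 0:
            raise ConfigurationError(
                f"effective input size {eff} not divisible by 2^{self.conv_blocks}"
            )


@dataclass
class Prediction:
    """Network output for one region."""

    p_suspicious: float
    location_probs: np.ndarray

    @property
    def location_index(self) -> int:
        # argmax with ties broken toward the first class index
        return int(np.argmax(self.location_probs))

    def is_suspicious(self, threshold: float = 0.5) -> bool:
        return self.p_suspicious >= threshold


class MultiTaskCnn:
    """The two-head network; parameters live in a flat named dict."""

    def __init__(self, cfg: ModelConfig, seed: int = 0,
                 location_classes: list[str] | None = None):
        self.cfg = cfg
        self.location_classes = location_classes
        rng = np.random.default_rng(seed)
        p: dict[str, np.ndarray] = {}
        ch = cfg.input_channels
        size = cfg.input_size // (2 if cfg.pool_first else 1)
        self.block_filters: list[int] = []
        for i in range(cfg.conv_blocks):
            f = min(cfg.base_filters * 2**i, cfg.max_filters)
            p[f"conv{i}_w"] = nn.he_init(rng, (f, ch, 3, 3), fan_in=ch * 9)
            p[f"conv{i}_b"] = np.zeros(f, dtype=np.float32)
            self.block_filters.append(f)
            ch = f
            size //= 2
        self.feat_dim = ch * size * size
        susp_in = self.feat_dim + (1 if cfg.dual_tracer else 0)
        p["susp_fc1_w"] = nn.he_init(rng, (susp_in, cfg.fc_width), fan_in=susp_in)
        p["susp_fc1_b"] = np.zeros(cfg.fc_width, dtype=np.float32)
        p["susp_out_w"] = nn.he_init(rng, (cfg.fc_width, 1), fan_in=cfg.fc_width)
        p["susp_out_b"] = np.zeros(1, dtype=np.float32)
        p["loc_fc1_w"] = nn.he_init(rng, (self.feat_dim, cfg.fc_width),
                                    fan_in=self.feat_dim)
        p["loc_fc1_b"] = np.zeros(cfg.fc_width, dtype=np.float32)
        p["loc_out_w"] = nn.he_init(rng, (cfg.fc_width, cfg.n_location_classes),
                                    fan_in=cfg.fc_width)
        p["loc_out_b"] = np.zeros(cfg.n_location_classes, dtype=np.float32)
        self.params = p

    # -- forward/backward -----------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        expect = (self.cfg.input_channels, self.cfg.input_size, self.cfg.input_size)
        if x.ndim == 3:
            x = x[None]
        if x.shape[1:] != expect:
            raise ConfigurationError(f"input shape {x.shape[1:]} != expected {expect}")
        return x

    def forward(self, x: np.ndarray, tracer: np.ndarray | None = None,
                train: bool = False, rng: np.random.Generator | None = None):
        """Returns (p_suspicious (N,), location_probs (N,K), cache)."""
        x = self._check_input(x)
        n = x.shape[0]
        p = self.params
        caches = []
        h = x
        if self.cfg.pool_first:
            # max (not average) pooling: preserves whether the stack centre
            # is the local uptake maximum, the cue separating lesion-centred
            # regions from rim fragments of a hotter neighbour
            h, _ = nn.maxpool2_forward(h)
        for i in range(self.cfg.conv_blocks):
            h, c_conv = nn.conv2d_forward(h, p[f"conv{i}_w"], p[f"conv{i}_b"])
            h, c_relu = nn.relu_forward(h)
            h, c_pool = nn.maxpool2_forward(h)
            caches.append((c_conv, c_relu, c_pool))
        feat = h.reshape(n, self.feat_dim)

        if self.cfg.dual_tracer:
            if tracer is None:
                raise ConfigurationError("dual_tracer model requires a tracer input")
            tcol = np.asarray(tracer, dtype=np.float32).reshape(n, 1)
            fs = np.concatenate([feat, tcol], axis=1)
        else:
            fs = feat
        s1, cs1 = nn.dense_forward(fs, p["susp_fc1_w"], p["susp_fc1_b"])
        s1a, ms1 = nn.relu_forward(s1)
        drop_mask = None
        if train and self.cfg.dropout > 0:
            keep = 1.0 - self.cfg.dropout
            gen = rng or np.random.default_rng(0)
            drop_mask = (gen.random(s1a.shape) < keep).astype(np.float32) / keep
            s1a = s1a * drop_mask
        zs, czs = nn.dense_forward(s1a, p["susp_out_w"], p["susp_out_b"])
        p_susp = nn.sigmoid(zs[:, 0])

        l1, cl1 = nn.dense_forward(feat, p["loc_fc1_w"], p["loc_fc1_b"])
        l1a, ml1 = nn.relu_forward(l1)
        zl, czl = nn.dense_forward(l1a, p["loc_out_w"], p["loc_out_b"])
        probs = nn.softmax(zl)

        cache = dict(
            caches=caches, feat_shape=h.shape, n=n,
            cs1=cs1, ms1=ms1, czs=czs, cl1=cl1, ml1=ml1, czl=czl,
            zs=zs, drop_mask=drop_mask,
        )
        return p_susp, probs, cache

    def backward(self, cache, dzs: np.ndarray, dzl: np.ndarray) -> dict:
        """Backpropagate logit gradients; returns named gradient dict."""
        p = self.params
        grads: dict[str, np.ndarray] = {}
        # suspicious head
        ds1a, grads["susp_out_w"], grads["susp_out_b"] = nn.dense_backward(
            dzs, cache["czs"], p["susp_out_w"]
        )
        if cache["drop_mask"] is not None:
            ds1a = ds1a * cache["drop_mask"]
        ds1 = nn.relu_backward(ds1a, cache["ms1"])
        dfs, grads["susp_fc1_w"], grads["susp_fc1_b"] = nn.dense_backward(
            ds1, cache["cs1"], p["susp_fc1_w"]
        )
        dfeat_s = dfs[:, : self.feat_dim]  # tracer column carries no upstream grad
        # location head
        dl1a, grads["loc_out_w"], grads["loc_out_b"] = nn.dense_backward(
            dzl, cache["czl"], p["loc_out_w"]
        )
        dl1 = nn.relu_backward(dl1a, cache["ml1"])
        dfeat_l, grads["loc_fc1_w"], grads["loc_fc1_b"] = nn.dense_backward(
            dl1, cache["cl1"], p["loc_fc1_w"]
        )
        dh = (dfeat_s + dfeat_l).reshape(cache["feat_shape"])
        for i in reversed(range(self.cfg.conv_blocks)):
            c_conv, c_relu, c_pool = cache["caches"][i]
            dh = nn.maxpool2_backward(dh, c_pool)
            dh = nn.relu_backward(dh, c_relu)
            dh, grads[f"conv{i}_w"], grads[f"conv{i}_b"] = nn.conv2d_backward(
                dh, c_conv, p[f"conv{i}_w"]
            )
        return grads

    def loss_and_grads(self, x, tracer, y_susp, y_loc,
                       loss_weights: tuple[float, float] = (1.0, 1.0),
                       pos_weight: float = 1.0,
                       train: bool = True,
                       rng: np.random.Generator | None = None):
        """Joint loss and gradients for one batch.

        ``y_susp`` is 0/1; ``y_loc`` is a class index or -1 for regions
        without a location label (their location loss is masked to zero).
        Total loss = w_susp * BCE + w_loc * masked CE.
        """
        y_susp = np.asarray(y_susp, dtype=np.float32).reshape(-1)
        y_loc = np.asarray(y_loc, dtype=np.int64).reshape(-1)
        p_susp, probs, cache = self.forward(x, tracer, train=train, rng=rng)
        ls, dzs = nn.bce_loss(p_susp, y_susp, cache["zs"], pos_weight=pos_weight)
        ll, dzl = nn.masked_ce_loss(probs, y_loc)
        ws, wl = loss_weights
        grads = self.backward(cache, (ws * dzs)[:, None], wl * dzl)
        return ws * ls + wl * ll, grads, (p_susp, probs)

    # -- inference ------------------------------------------------------------

    def predict_batch(self, x: np.ndarray, tracer=None):
        p_susp, probs, _ = self.forward(x, tracer, train=False)
        return p_susp, probs

    def clone(self) -> "MultiTaskCnn":
        other = MultiTaskCnn(self.cfg, seed=0, location_classes=self.location_classes)
        other.params = {k: v.copy() for k, v in self.params.items()}
        return other

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        """Weights as .npz with a JSON config sidecar (.json)."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.params)
        sidecar = {
            "config": asdict(self.cfg),
            "location_classes": self.location_classes,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "MultiTaskCnn":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg = ModelConfig(**sidecar["config"])
        model = cls(cfg, seed=0, location_classes=sidecar["location_classes"])
        with np.load(path.with_suffix(".npz")) as data:
            model.params = {k: data[k].copy() for k in data.files}
        return model


def build_model(cfg: ModelConfig, seed: int = 0,
                location_classes: list[str] | None = None) -> MultiTaskCnn:
    """Construct the network with seeded He initialization."""
    if location_classes is not None and len(location_classes) != cfg.n_location_classes:
        raise ConfigurationError("location_classes length != n_location_classes")
    return MultiTaskCnn(cfg, seed=seed, location_classes=location_classes)


def predict(model: MultiTaskCnn, stack: MprStack, tracer: str = "PSMA") -> Prediction:
    """Deterministic single-region prediction (evaluation mode)."""
    x = stack.as_network_input()[None]
    t = np.array([TRACER_BIT[tracer]]) if model.cfg.dual_tracer else None
    p_susp, probs, _ = model.forward(x, t, train=False)
    return Prediction(p_suspicious=float(p_susp[0]), location_probs=probs[0])
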