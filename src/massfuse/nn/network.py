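"""3D residual classifier with per-stage attention.

Layer sequence: stem conv (k=3, s=1, p=1) keeping the first stage width, then
per stage ``res_block x N -> CBAM -> downsample conv (k=2, s=2, p=0)`` (the
downsample doubles the channel width and halves each spatial side; the last
stage has no downsample), then flatten and a fully-connected head ending in a
2-way softmax. Residual blocks are two conv-batchnorm-ReLU units plus an
identity shortcut, so zeroing the branch weights makes the block an exact
identity map.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import yaml

from .layers import Conv3d, BatchNorm3d, Flatten, Linear, Module, ReLU, Sequential, softmax
from .cbam import CBAM3d

#: stage plan (res_block_count, channel_width, spatial_side) of the published table
CANONICAL_STAGE_PLAN: tuple[tuple[int, int, int], ...] = (
    (2, 8, 64), (4, 16, 32), (4, 32, 16), (4, 64, 8), (4, 128, 4),
)
CANONICAL_FC_WIDTHS: tuple[int, ...] = (8192, 2048, 512)


@dataclass
class NetworkConfig:
    in_channels: int = 8
    stage_plan: tuple[tuple[int, int, int], ...] = CANONICAL_STAGE_PLAN
    fc_widths: tuple[int, ...] = CANONICAL_FC_WIDTHS
    n_classes: int = 2
    channel_attention: bool = True
    spatial_attention: bool = True
    channel_gate: str = "sigmoid"  # "softmax" variant available for fidelity runs
    spatial_kernel: int = 7
    reduction: int = 8
    min_hidden: int = 4  # bottleneck never collapses below this many units
    dtype: str = "float32"

    def validate(self) -> None:
        if self.in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        if not self.stage_plan:
            raise ValueError("stage_plan must contain at least one stage")
        for i, (blocks, width, side) in enumerate(self.stage_plan):
            if blocks < 1 or width < 1 or side < 1:
                raise ValueError(f"stage {i} has non-positive entries")
            if i > 0:
                prev_side = self.stage_plan[i - 1][2]
                if side * 2 != prev_side:
                    raise ValueError(
                        f"stage {i}: side {side} must be half of previous side {prev_side}")
        last_blocks, last_width, last_side = self.stage_plan[-1]
        flat = last_width * last_side ** 3
        if self.fc_widths[0] != flat:
            raise ValueError(
                f"fc_widths[0]={self.fc_widths[0]} must equal flatten width {flat}")
        if self.n_classes != 2:
            raise ValueError("only binary classification is supported")
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd")

    @property
    def flatten_width(self) -> int:
        _, width, side = self.stage_plan[-1]
        return width * side ** 3

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["stage_plan"] = tuple(tuple(s) for s in raw["stage_plan"])
        raw["fc_widths"] = tuple(raw["fc_widths"])
        return cls(**raw)


@dataclass
class Prediction:
    p_benign: float
    p_malignant: float
    predicted_label: str
    case_id: str = ""

    def __post_init__(self) -> None:
        total = self.p_benign + self.p_malignant
        if not np.isclose(total, 1.0, atol=1e-5):
            raise ValueError(f"probabilities must sum to 1, got {total}")


class ResBlock3d(Module):
    """x + f(x) with f = (conv-bn-ReLU) x2; final BN scale zero-initialised."""

    def __init__(self, channels: int, *, rng: np.random.Generator, dtype) -> None:
        self.branch = Sequential(
            Conv3d(channels, channels, 3, stride=1, padding=1, rng=rng, dtype=dtype),
            BatchNorm3d(channels, dtype=dtype),
            ReLU(),
            Conv3d(channels, channels, 3, stride=1, padding=1, rng=rng, dtype=dtype),
            BatchNorm3d(channels, dtype=dtype, zero_init_scale=True),
            ReLU(),
        )

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.branch(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad + self.branch.backward(grad)


class MassClassifier3d(Module):
    """The full network; ``forward_with_shapes`` exposes per-layer output sizes."""

    def __init__(self, config: NetworkConfig, *, seed: int = 0) -> None:
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        dtype = np.dtype(config.dtype)
        first_width = config.stage_plan[0][1]
        self.stem = Conv3d(config.in_channels, first_width, 3, stride=1, padding=1,
                           rng=rng, dtype=dtype)
        self.stages: list[Module] = []
        self.downsamples: list[Module] = []
        self.attentions: list[Module] = []
        for i, (blocks, width, _side) in enumerate(config.stage_plan):
            self.stages.append(Sequential(
                *[ResBlock3d(width, rng=rng, dtype=dtype) for _ in range(blocks)]))
            red = min(config.reduction, max(width // config.min_hidden, 1))
            self.attentions.append(CBAM3d(
                width, reduction=red, spatial_kernel=config.spatial_kernel,
                gate=config.channel_gate, use_channel=config.channel_attention,
                use_spatial=config.spatial_attention, rng=rng, dtype=dtype))
            if i + 1 < len(config.stage_plan):
                next_width = config.stage_plan[i + 1][1]
                self.downsamples.append(Conv3d(width, next_width, 2, stride=2,
                                               padding=0, rng=rng, dtype=dtype))
        self.flatten = Flatten()
        head: list[Module] = []
        widths = list(config.fc_widths) + [config.n_classes]
        for j, (w_in, w_out) in enumerate(zip(widths[:-1], widths[1:])):
            head.append(Linear(w_in, w_out, rng=rng, dtype=dtype))
            if j + 1 < len(widths) - 1:
                head.append(ReLU())
        self.head = Sequential(*head)

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Return logits of shape (N, n_classes)."""
        x = np.asarray(x, dtype=self.config.dtype)
        if x.ndim == 4:
            x = x[None]
        if x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} channels, got {x.shape[1]}")
        x = self.stem(x)
        for i, (stage, attn) in enumerate(zip(self.stages, self.attentions)):
            x = stage(x)
            x = attn(x)
            if i < len(self.downsamples):
                x = self.downsamples[i](x)
        x = self.flatten(x)
        return self.head(x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.head.backward(grad)
        grad = self.flatten.backward(grad)
        for i in reversed(range(len(self.stages))):
            if i < len(self.downsamples):
                grad = self.downsamples[i].backward(grad)
            grad = self.attentions[i].backward(grad)
            grad = self.stages[i].backward(grad)
        return self.stem.backward(grad)

    def forward_with_shapes(self, x: np.ndarray) -> tuple[np.ndarray, list[tuple[str, tuple[int, ...]]]]:
        """Forward pass recording (layer_name, per-sample output shape) rows."""
        x = np.asarray(x, dtype=self.config.dtype)
        if x.ndim == 4:
            x = x[None]
        rows: list[tuple[str, tuple[int, ...]]] = []
        x = self.stem(x)
        rows.append(("conv", x.shape[1:]))
        for i, (stage, attn) in enumerate(zip(self.stages, self.attentions)):
            x = stage(x)
            rows.append((f"res_conv*{len(stage.layers)}", x.shape[1:]))
            x = attn(x)
            rows.append(("3D_CBAM", x.shape[1:]))
            if i < len(self.downsamples):
                x = self.downsamples[i](x)
                rows.append(("conv", x.shape[1:]))
        x = self.flatten(x)
        rows.append(("Flatten", x.shape[1:]))
        for layer in self.head.layers:
            x = layer(x)
            if isinstance(layer, Linear):
                rows.append(("Full connection", x.shape[1:]))
        rows[-1] = ("Softmax", x.shape[1:])
        return x, rows

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        self.set_training(False)
        return softmax(self.forward(x), axis=1)

    def state_dict(self) -> list[np.ndarray]:
        state = [p.data.copy() for p in self.params()]
        for bn in self._batchnorms():
            state.append(bn.running_mean.copy())
            state.append(bn.running_var.copy())
        return state

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.params()
        bns = self._batchnorms()
        if len(state) != len(params) + 2 * len(bns):
            raise ValueError("state does not match network layout")
        for p, arr in zip(params, state[:len(params)]):
            p.data[...] = arr
        rest = state[len(params):]
        for i, bn in enumerate(bns):
            bn.running_mean[...] = rest[2 * i]
            bn.running_var[...] = rest[2 * i + 1]

    def _batchnorms(self) -> list[BatchNorm3d]:
        out: list[BatchNorm3d] = []

        def walk(mod: Module) -> None:
            if isinstance(mod, BatchNorm3d):
                out.append(mod)
            for sub in mod.submodules():
                walk(sub)

        walk(self)
        return out


def default_config_for(in_channels: int, side: int = 64) -> NetworkConfig:
    """The published plan for 64-cubed inputs; a proportionally scaled-down
    plan (one res block per stage, widths doubling from 8, sides halving to 4)
    for smaller inputs."""
    if side == 64:
        return NetworkConfig(in_channels=in_channels)
    if side < 8 or side & (side - 1):
        raise ValueError(f"input side must be a power of two >= 8, got {side}")
    plan, width = [], 8
    while side >= 4:
        plan.append((1, width, side))
        width *= 2
        side //= 2
    last_blocks, last_width, last_side = plan[-1]
    flat = last_width * last_side ** 3
    return NetworkConfig(in_channels=in_channels, stage_plan=tuple(plan),
                         fc_widths=(flat, max(flat // 32, 16)),
                         spatial_kernel=3, reduction=4)


def build_network(config: NetworkConfig, *, seed: int = 0) -> MassClassifier3d:
    return MassClassifier3d(config, seed=seed)


def predict(network: MassClassifier3d, channels: np.ndarray,
            case_id: str = "") -> Prediction:
    """Classify one channel-stacked input; ties go to malignant (P1 <= P2)."""
    probs = network.predict_proba(channels[None] if channels.ndim == 4 else channels)[0]
    p1, p2 = float(probs[0]), float(probs[1])
    label = "benign" if p1 > p2 else "malignant"
    return Prediction(p_benign=p1, p_malignant=p2, predicted_label=label,
                      case_id=case_id)
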