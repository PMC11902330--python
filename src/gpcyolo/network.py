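"""Declarative model assembly, profiling, serialization and inference.

A model is described by an ordered list of :class:`LayerSpec` entries
forming a DAG (each layer consumes earlier layers only), with nominal
channel counts that are scaled by the config's width multiple — e.g. a
nominal 256 becomes 64 real channels at the "n"-scale width of 0.25.
Built-in variants cover the stock single-stage baseline, each ablation
step (GSConv downsampling, PConv feature blocks, the reduced-width
cross-scale fusion neck, parameter-free attention) and the full
lightweight detector:

====================  ===========================================
``baseline``          stock anchor-free v8-style detector (nano)
``+A``                GSConv replaces the stride-2 downsampling convs
``+A+B``              ... and every C2f becomes C2f-PC
``+A+B+C``            ... and the neck becomes the 64-wide CCFF
``+A+B+C+D`` (gpc)    ... plus SimAM on the three neck outputs
====================  ===========================================

Profiling reports exact parameter counts and GFLOPs under the package's
op-cost model (2 ops per conv multiply-accumulate, 4 per normalized
element, 6 per SiLU element; see :mod:`gpcyolo.nn.layers`).
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .boxes import Box
from .nn import layers as L
from .nn.tensor import Tensor, no_grad

__all__ = [
    "LayerSpec", "ModelConfig", "ProfileReport", "Model", "VARIANT_ALIASES",
    "variant_config", "build_model", "count_parameters", "profile_flops",
    "save_weights", "load_weights", "predict", "nms", "letterbox",
    "decode_predictions",
]

_BLOCK_KINDS = {"ConvBNAct", "GSConv", "C2f", "C2f-PC", "SPPF", "SimAM",
                "Upsample", "Concat", "Detect"}


@dataclass
class LayerSpec:
    """One layer of the architecture DAG.

    ``from_`` holds indices of input layers (-1 = previous); ``args`` are
    nominal arguments in the order the block expects (e.g. ``[c2, k, s]``
    for a convolution); ``repeats`` is the nominal bottleneck count for
    C2f-style blocks, scaled by the depth multiple.
    """

    index: int
    block_kind: str
    from_: List[int] = field(default_factory=lambda: [-1])
    args: List = field(default_factory=list)
    repeats: int = 1

    def __post_init__(self):
        if self.block_kind not in _BLOCK_KINDS:
            raise ValueError(f"unknown block kind {self.block_kind!r}")


@dataclass
class ModelConfig:
    """Complete declarative description of a detector variant."""

    num_classes: int = 3
    input_size: int = 640
    width_multiple: float = 0.25
    depth_multiple: float = 0.33
    max_channels: int = 1024
    layers: List[LayerSpec] = field(default_factory=list)
    variant_name: str = "custom"

    def scaled_channels(self, c: int) -> int:
        c = min(c, self.max_channels) * self.width_multiple
        return max(int(np.ceil(c / 8) * 8) if c % 8 else int(c), 8)

    def scaled_repeats(self, n: int) -> int:
        return max(round(n * self.depth_multiple), 1) if n > 1 else n

    def to_dict(self) -> dict:
        return {
            "num_classes": self.num_classes,
            "input_size": self.input_size,
            "width_multiple": self.width_multiple,
            "depth_multiple": self.depth_multiple,
            "max_channels": self.max_channels,
            "variant_name": self.variant_name,
            "layers": [
                {"index": l.index, "block_kind": l.block_kind,
                 "from": list(l.from_), "args": list(l.args), "repeats": l.repeats}
                for l in self.layers
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        layers = [LayerSpec(x["index"], x["block_kind"], list(x["from"]),
                            list(x["args"]), x.get("repeats", 1))
                  for x in d["layers"]]
        return cls(d["num_classes"], d["input_size"], d["width_multiple"],
                   d["depth_multiple"], d["max_channels"], layers,
                   d.get("variant_name", "custom"))

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as f:
            yaml.safe_dump({"format_version": 1, **self.to_dict()}, f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        import yaml

        with open(path) as f:
            d = yaml.safe_load(f)
        return cls.from_dict(d)


@dataclass
class ProfileReport:
    total_params: int
    per_layer_params: List[Tuple[int, str, int]]
    gflops: float
    serialized_size_mb: float
    input_size: int

    def __str__(self) -> str:
        lines = [f"{'idx':>4} {'block':<12} {'params':>10}"]
        for i, kind, p in self.per_layer_params:
            lines.append(f"{i:>4} {kind:<12} {p:>10,}")
        lines.append(f"total params     {self.total_params:,}")
        lines.append(f"GFLOPs @ {self.input_size}   {self.gflops:.1f}")
        lines.append(f"fp16 size (MB)   {self.serialized_size_mb:.1f}")
        return "\n".join(lines)


# ---------------------------------------------------------------------
# built-in variants (nominal channels; width 0.25 scales 256 -> 64 etc.)
# ---------------------------------------------------------------------

def _backbone(down_kind: str, c2f_kind: str) -> List[tuple]:
    return [
        ("ConvBNAct", [-1], [64, 3, 2], 1),
        (down_kind, [-1], [128, 3, 2], 1),
        (c2f_kind, [-1], [128, True], 3),
        (down_kind, [-1], [256, 3, 2], 1),
        (c2f_kind, [-1], [256, True], 6),
        (down_kind, [-1], [512, 3, 2], 1),
        (c2f_kind, [-1], [512, True], 6),
        (down_kind, [-1], [1024, 3, 2], 1),
        (c2f_kind, [-1], [1024, True], 3),
        ("SPPF", [-1], [1024, 5], 1),
    ]


def _pan_neck(down_kind: str, c2f_kind: str) -> List[tuple]:
    return [
        ("Upsample", [-1], [], 1),
        ("Concat", [-1, 6], [], 1),
        (c2f_kind, [-1], [512, False], 3),
        ("Upsample", [-1], [], 1),
        ("Concat", [-1, 4], [], 1),
        (c2f_kind, [-1], [256, False], 3),      # 15: P3
        (down_kind, [-1], [256, 3, 2], 1),
        ("Concat", [-1, 12], [], 1),
        (c2f_kind, [-1], [512, False], 3),      # 18: P4
        (down_kind, [-1], [512, 3, 2], 1),
        ("Concat", [-1, 9], [], 1),
        (c2f_kind, [-1], [1024, False], 3),     # 21: P5
        ("Detect", [15, 18, 21], [], 1),
    ]


def _ccff_neck(simam: bool) -> List[tuple]:
    neck = [
        ("GSConv", [9], [256, 1, 1], 1),        # 10: P5 projection
        ("GSConv", [-1], [256, 1, 1], 1),       # 11: P5 lateral
        ("Upsample", [-1], [], 1),
        ("GSConv", [6], [256, 1, 1], 1),        # 13: P4 projection
        ("Concat", [12, 13], [], 1),
        ("C2f-PC", [-1], [256, False], 3),      # 15: top-down P4 fusion
        ("GSConv", [-1], [256, 1, 1], 1),       # 16: P4 lateral
        ("Upsample", [-1], [], 1),
        ("Concat", [17, 4], [], 1),
        ("C2f-PC", [-1], [256, False], 3),      # 19: P3 fusion
        ("GSConv", [19], [256, 3, 2], 1),       # 20: downsample P3 -> P4
        ("Concat", [-1, 16], [], 1),
        ("C2f-PC", [-1], [256, False], 3),      # 22: bottom-up P4 fusion
        ("GSConv", [-1], [256, 3, 2], 1),       # 23: downsample P4 -> P5
        ("Concat", [-1, 11], [], 1),
        ("C2f-PC", [-1], [256, False], 3),      # 25: bottom-up P5 fusion
    ]
    if simam:
        neck += [
            ("SimAM", [19], [], 1),             # 26
            ("SimAM", [22], [], 1),             # 27
            ("SimAM", [25], [], 1),             # 28
            ("Detect", [26, 27, 28], [], 1),
        ]
    else:
        neck += [("Detect", [19, 22, 25], [], 1)]
    return neck


def _variant_layers(name: str) -> List[tuple]:
    if name == "baseline":
        return _backbone("ConvBNAct", "C2f") + _pan_neck("ConvBNAct", "C2f")
    if name == "+A":
        return _backbone("GSConv", "C2f") + _pan_neck("GSConv", "C2f")
    if name == "+A+B":
        return _backbone("GSConv", "C2f-PC") + _pan_neck("GSConv", "C2f-PC")
    if name == "+A+B+C":
        return _backbone("GSConv", "C2f-PC") + _ccff_neck(simam=False)
    if name in ("+A+B+C+D", "gpc"):
        return _backbone("GSConv", "C2f-PC") + _ccff_neck(simam=True)
    raise KeyError(f"unknown variant {name!r}")


VARIANT_ALIASES: Dict[str, str] = {
    "baseline": "baseline", "yolov8n": "baseline",
    "+A": "+A", "gsconv": "+A",
    "+A+B": "+A+B",
    "+A+B+C": "+A+B+C",
    "+A+B+C+D": "+A+B+C+D", "gpc": "gpc", "gpc-yolo": "gpc",
}


def variant_config(name: str, num_classes: int = 3, input_size: int = 640) -> ModelConfig:
    """Config for a named built-in variant (see module docstring)."""
    key = VARIANT_ALIASES.get(name)
    if key is None:
        raise KeyError(f"unknown variant {name!r}; choose from {sorted(set(VARIANT_ALIASES))}")
    rows = _variant_layers(key)
    layers = [LayerSpec(i, kind, list(frm), list(args), rep)
              for i, (kind, frm, args, rep) in enumerate(rows)]
    return ModelConfig(num_classes=num_classes, input_size=input_size,
                       layers=layers, variant_name=key)


# ---------------------------------------------------------------------
# build + validate
# ---------------------------------------------------------------------

class Model:
    """An executable layer DAG with per-layer bookkeeping."""

    def __init__(self, cfg: ModelConfig, modules: List[L.Module],
                 froms: List[List[int]], strides: Tuple[int, ...],
                 out_ch: List[int]):
        self.cfg = cfg
        self._modules = modules
        self._froms = froms
        self.strides = strides
        self.out_ch = out_ch
        self.detect: L.Detect = modules[-1]  # validated as the single head

    def train(self):
        for m in self._modules:
            m.train()
        return self

    def eval(self):
        for m in self._modules:
            m.eval()
        return self

    def parameters(self):
        for m in self._modules:
            yield from m.parameters()

    def named_parameters(self):
        for i, m in enumerate(self._modules):
            for n, p in m.named_parameters():
                yield f"layer{i}.{n}", p

    def param_count(self) -> int:
        return sum(m.param_count() for m in self._modules)

    def state_dict(self) -> Dict[str, np.ndarray]:
        out = {}
        for i, m in enumerate(self._modules):
            out.update(m.state_dict(f"layer{i}."))
        return out

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for i, m in enumerate(self._modules):
            m.load_state_dict(state, f"layer{i}.")

    def forward(self, x: Union[np.ndarray, Tensor]) -> List[Tensor]:
        """Run the DAG; returns the head's per-scale raw prediction maps."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        outputs: List[Optional[Tensor]] = [None] * len(self._modules)
        y = x
        for i, (m, frm) in enumerate(zip(self._modules, self._froms)):
            if isinstance(m, L.Concat):
                y = m([outputs[j] for j in frm])
            elif isinstance(m, L.Detect):
                y = m([outputs[j] for j in frm])
            else:
                src = y if frm == [-1] else outputs[frm[0]]
                y = m(src)
            outputs[i] = y
        return y

    __call__ = forward


def _resolve_from(frm: List[int], index: int) -> List[int]:
    out = []
    for j in frm:
        jj = index - 1 if j == -1 else j
        if jj < 0 or jj >= index:
            raise ValueError(
                f"layer {index}: from-index {j} does not reference an earlier layer")
        out.append(jj)
    return out


def build_model(cfg: ModelConfig, seed: int = 0) -> Model:
    """Instantiate a config: validates the DAG and channel closure, checks
    the single-head/three-scale contract, then allocates weights."""
    if cfg.num_classes < 1:
        raise ValueError("num_classes must be >= 1")
    rng = np.random.default_rng(seed)
    modules: List[L.Module] = []
    froms: List[List[int]] = []
    ch: List[int] = []       # out channels per layer
    st: List[int] = []       # stride (vs input) per layer
    detect_strides: Tuple[int, ...] = ()
    n_detect = 0
    for spec in cfg.layers:
        i = spec.index
        frm = _resolve_from(spec.from_, i) if i > 0 or spec.from_ != [-1] else []
        if i == 0:
            frm = []
            cin, sin = 3, 1
        elif spec.block_kind in ("Concat", "Detect"):
            cin, sin = [ch[j] for j in frm], [st[j] for j in frm]
        else:
            cin, sin = ch[frm[0]], st[frm[0]]
        kind = spec.block_kind
        if kind == "ConvBNAct":
            c2 = cfg.scaled_channels(spec.args[0])
            k, s = spec.args[1], spec.args[2]
            m = L.ConvBNAct(cin, c2, k, s, rng=rng)
            cout, sout = c2, sin * s
        elif kind == "GSConv":
            c2 = cfg.scaled_channels(spec.args[0])
            k, s = spec.args[1], spec.args[2]
            m = L.GSConv(cin, c2, k, s, rng=rng)
            cout, sout = c2, sin * s
        elif kind in ("C2f", "C2f-PC"):
            c2 = cfg.scaled_channels(spec.args[0])
            shortcut = bool(spec.args[1]) if len(spec.args) > 1 else False
            n = cfg.scaled_repeats(spec.repeats)
            m = L.C2f(cin, c2, n, shortcut, pc=(kind == "C2f-PC"), rng=rng)
            cout, sout = c2, sin
        elif kind == "SPPF":
            c2 = cfg.scaled_channels(spec.args[0])
            m = L.SPPF(cin, c2, spec.args[1] if len(spec.args) > 1 else 5, rng=rng)
            cout, sout = c2, sin
        elif kind == "SimAM":
            m = L.SimAM(*(spec.args or []))
            cout, sout = cin, sin
        elif kind == "Upsample":
            m = L.Upsample()
            if sin % 2:
                raise ValueError(f"layer {i}: cannot upsample a stride-{sin} map")
            cout, sout = cin, sin // 2
        elif kind == "Concat":
            if len(set(sin)) != 1:
                raise ValueError(
                    f"layer {i}: concat inputs have mismatched strides {sin}")
            m = L.Concat()
            cout, sout = sum(cin), sin[0]
        elif kind == "Detect":
            n_detect += 1
            if sorted(sin) != [8, 16, 32]:
                raise ValueError(
                    f"head must consume strides 8/16/32, got {sorted(sin)}")
            order = np.argsort(sin)
            frm = [frm[j] for j in order]
            detect_strides = tuple(sorted(sin))
            m = L.Detect(cfg.num_classes, tuple(ch[j] for j in frm),
                         detect_strides, rng=rng)
            cout, sout = 0, 0
        else:  # pragma: no cover - guarded by LayerSpec
            raise ValueError(kind)
        modules.append(m)
        froms.append(frm if frm else [-1])
        ch.append(cout)
        st.append(sout)
    if n_detect != 1 or not isinstance(modules[-1], L.Detect):
        raise ValueError("config must end with exactly one Detect head")
    return Model(cfg, modules, froms, detect_strides, ch)


def count_parameters(model: Model) -> int:
    """Exact number of weight scalars in the model."""
    return model.param_count()


def profile_flops(model: Model, input_size: Optional[int] = None) -> ProfileReport:
    """Propagate feature-map sizes and sum per-layer costs."""
    size = input_size or model.cfg.input_size
    if size % 32:
        raise ValueError(f"input size must be divisible by 32, got {size}")
    hw: List[Tuple[int, int]] = []
    total = 0
    per_layer = []
    for i, (m, frm, spec) in enumerate(zip(model._modules, model._froms, model.cfg.layers)):
        if i == 0:
            h = w = size
        elif isinstance(m, (L.Concat, L.Detect)):
            h, w = hw[frm[0]]
        else:
            h, w = hw[frm[0]]
        if isinstance(m, L.Detect):
            f = sum(m.flops_scale(j, *hw[src]) for j, src in enumerate(frm))
            out_hw = (0, 0)
        else:
            f, out_hw = m.flops(h, w)
        total += f
        hw.append(out_hw)
        per_layer.append((i, spec.block_kind, m.param_count()))
    params = model.param_count()
    return ProfileReport(
        total_params=params,
        per_layer_params=per_layer,
        gflops=total / 1e9,
        serialized_size_mb=params * 2 / 1e6,  # half-precision export
        input_size=size,
    )


# ---------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------

_FORMAT_VERSION = 1


def save_weights(model: Model, path, half: bool = False) -> None:
    """Write a single-file checkpoint (embedded config + format version).

    ``half=True`` stores float16 weights — the deployment/export mode whose
    file size the profiler's ``serialized_size_mb`` estimates.
    """
    state = model.state_dict()
    meta = {"format_version": _FORMAT_VERSION, "half": half,
            "config": model.cfg.to_dict()}
    arrays = {k: (v.astype(np.float16) if half else v) for k, v in state.items()}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_weights(path, seed: int = 0) -> Model:
    """Rebuild a model from a checkpoint; fails loudly on corrupt files."""
    try:
        with np.load(path) as z:
            arrays = {k: z[k] for k in z.files}
    except (zipfile.BadZipFile, OSError, ValueError, EOFError) as e:
        raise ValueError(f"corrupt or truncated checkpoint {path!r}: {e}") from e
    if "__meta__" not in arrays:
        raise ValueError(f"{path!r} is not a model checkpoint (missing metadata)")
    meta = json.loads(arrays.pop("__meta__").tobytes().decode())
    if meta.get("format_version") != _FORMAT_VERSION:
        raise ValueError(
            f"checkpoint format version {meta.get('format_version')} "
            f"not supported (expected {_FORMAT_VERSION})")
    cfg = ModelConfig.from_dict(meta["config"])
    model = build_model(cfg, seed=seed)
    state = {k: v.astype(np.float32) for k, v in arrays.items()}
    model.load_state_dict(state)
    return model


# ---------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------

def letterbox(img: np.ndarray, size: int) -> Tuple[np.ndarray, float, Tuple[float, float]]:
    """Resize (nearest) keeping aspect ratio and pad to ``size`` x ``size``.

    Returns the padded image, the scale gain and the (dx, dy) padding in
    target pixels, enough to map boxes back to source coordinates.
    """
    h, w = img.shape[:2]
    if h == 0 or w == 0:
        raise ValueError("empty image")
    r = min(size / h, size / w)
    nh, nw = max(1, round(h * r)), max(1, round(w * r))
    ys = (np.arange(nh) / r).astype(int).clip(0, h - 1)
    xs = (np.arange(nw) / r).astype(int).clip(0, w - 1)
    resized = img[ys][:, xs]
    out = np.full((size, size) + img.shape[2:], 114, dtype=img.dtype)
    dy, dx = (size - nh) // 2, (size - nw) // 2
    out[dy:dy + nh, dx:dx + nw] = resized
    return out, r, (float(dx), float(dy))


def make_anchors(shapes: Sequence[Tuple[int, int]], strides: Sequence[int],
                 offset: float = 0.5) -> Tuple[np.ndarray, np.ndarray]:
    """Grid-cell center points (in cell units) and per-anchor strides."""
    pts, sts = [], []
    for (h, w), s in zip(shapes, strides):
        gy, gx = np.meshgrid(np.arange(h) + offset, np.arange(w) + offset,
                             indexing="ij")
        pts.append(np.stack([gx.ravel(), gy.ravel()], axis=-1))
        sts.append(np.full((h * w, 1), s, dtype=np.float32))
    return (np.concatenate(pts).astype(np.float32), np.concatenate(sts))


def decode_predictions(outs: List[np.ndarray], strides: Sequence[int], nc: int
                       ) -> Tuple[np.ndarray, np.ndarray]:
    """Raw per-scale maps -> (boxes_xyxy [N,A,4] in input pixels,
    class scores [N,A,nc] after sigmoid)."""
    reg = L.Detect.REG_MAX
    shapes = [o.shape[2:] for o in outs]
    pts, sts = make_anchors(shapes, strides)
    flat = [o.reshape(o.shape[0], o.shape[1], -1) for o in outs]
    cat = np.concatenate(flat, axis=2)                       # (N, 4*reg+nc, A)
    dist, cls = cat[:, : 4 * reg], cat[:, 4 * reg:]
    n, _, a = dist.shape
    d = dist.reshape(n, 4, reg, a)
    d = d - d.max(axis=2, keepdims=True)
    e = np.exp(d)
    p = e / e.sum(axis=2, keepdims=True)
    ltrb = (p * np.arange(reg, dtype=np.float32).reshape(1, 1, reg, 1)).sum(axis=2)
    ltrb = ltrb.transpose(0, 2, 1)                           # (N, A, 4)
    xy1 = pts[None] - ltrb[..., :2]
    xy2 = pts[None] + ltrb[..., 2:]
    boxes = np.concatenate([xy1, xy2], axis=-1) * sts[None]  # input pixels
    scores = 1.0 / (1.0 + np.exp(-cls.transpose(0, 2, 1)))
    return boxes.astype(np.float32), scores.astype(np.float32)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> np.ndarray:
    """Greedy non-maximum suppression on xyxy boxes; returns kept indices."""
    order = np.argsort(-scores, kind="stable")
    x1, y1, x2, y2 = boxes.T
    areas = np.maximum(x2 - x1, 0) * np.maximum(y2 - y1, 0)
    keep = []
    while order.size:
        i = order[0]
        keep.append(i)
        rest = order[1:]
        iw = np.minimum(x2[i], x2[rest]) - np.maximum(x1[i], x1[rest])
        ih = np.minimum(y2[i], y2[rest]) - np.maximum(y1[i], y1[rest])
        inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
        union = areas[i] + areas[rest] - inter
        ov = np.where(union > 0, inter / union, 0.0)
        order = rest[ov <= iou_thresh]
    return np.asarray(keep, dtype=int)


def predict(model: Model, image: np.ndarray, conf_thresh: float = 0.25,
            iou_thresh: float = 0.45, max_det: int = 300) -> List[Box]:
    """Detect objects in one HxWx3 uint8 image.

    Letterboxes to the model input size, decodes, filters by confidence and
    applies class-wise NMS; boxes are returned in original-image pixels
    (center form), clipped to the image bounds.
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {image.shape}")
    h0, w0 = image.shape[:2]
    size = model.cfg.input_size
    padded, r, (dx, dy) = letterbox(image, size)
    x = padded.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
    model.eval()
    with no_grad():
        outs = model(x)
    boxes, scores = decode_predictions([o.data for o in outs], model.strides,
                                       model.cfg.num_classes)
    boxes, scores = boxes[0], scores[0]
    cls_id = scores.argmax(axis=1)
    conf = scores.max(axis=1)
    m = conf >= conf_thresh
    boxes, cls_id, conf = boxes[m], cls_id[m], conf[m]
    results: List[Box] = []
    for c in np.unique(cls_id):
        sel = cls_id == c
        keep = nms(boxes[sel], conf[sel], iou_thresh)
        for i in keep:
            x1, y1, x2, y2 = boxes[sel][i]
            # undo letterbox
            x1, x2 = (x1 - dx) / r, (x2 - dx) / r
            y1, y2 = (y1 - dy) / r, (y2 - dy) / r
            x1, x2 = np.clip([x1, x2], 0, w0)
            y1, y2 = np.clip([y1, y2], 0, h0)
            if x2 <= x1 or y2 <= y1:
                continue
            results.append(Box((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1,
                               int(c), float(np.clip(conf[sel][i], 0, 1))))
    results.sort(key=lambda b: -(b.confidence or 0))
    return results[:max_det]
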