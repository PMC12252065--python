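"""Encoders and heads: residual TCN, residual autoencoder, Siamese wrappers.

Two encoder families cover all six paradigms:

* a residual temporal convolutional network on raw windows — stacked blocks of
  (causal dilated conv -> BN -> ReLU) x2 with an identity or linear-projection
  skip, dilation doubling per block, temporal max-pooling after every
  ``pool_every`` blocks, global average pooling and a fully connected layer to
  the embedding size H;
* a residual fully connected autoencoder on handcrafted feature vectors — an
  encoder of residual FC blocks with decreasing widths ending at H and a plain
  FC decoder widening back to the input size.

Siamese wrappers share every trunk parameter across both branches and add one
(activity) or two (activity + person) fully connected projection heads.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn import (Module, Linear, Conv1dCausal, BatchNorm1d, MaxPool1d,
                 Tensor, astensor, concat)

__all__ = [
    "EncoderSpec", "ModelBundle", "TCNEncoder", "ResidualAutoencoder",
    "SiameseModel", "build_tcn_encoder", "build_residual_autoencoder",
    "build_siamese", "save_bundle", "load_bundle",
]


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture hyperparameters shared by the encoder builders.

    ``input_shape`` is (W, C) for raw-signal encoders or an int (7*C) for
    feature-space encoders.
    """

    input_shape: tuple[int, int] | int
    embedding_dim: int = 32
    n_tcn_blocks: int = 4
    channels_per_block: tuple[int, ...] = (16, 16, 32, 32)
    kernel_size: int = 5
    pool_every: int = 2
    hidden_dims: tuple[int, ...] = (128, 64)

    def __post_init__(self):
        if self.embedding_dim < 2:
            raise ValueError("embedding_dim must be >= 2")
        if self.kernel_size < 2:
            raise ValueError("kernel_size must be >= 2 for TCN encoders")
        if len(self.channels_per_block) != self.n_tcn_blocks:
            raise ValueError("channels_per_block must list one width per block")
        if not self.hidden_dims:
            raise ValueError("hidden_dims must be nonempty")


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), 77, stream]))


class _TCNBlock(Module):
    """(conv -> BN -> ReLU) x2 with residual skip; no post-add activation, so
    zeroing the second conv reduces the block to its skip path."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, dilation: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv1dCausal(in_ch, out_ch, kernel, rng, dilation=dilation)
        self.bn1 = BatchNorm1d(out_ch)
        self.conv2 = Conv1dCausal(out_ch, out_ch, kernel, rng, dilation=dilation)
        self.bn2 = BatchNorm1d(out_ch)
        if in_ch != out_ch:
            self.proj = Conv1dCausal(in_ch, out_ch, 1, rng)  # linear 1x1 projection
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h)).relu()
        skip = x if self.proj is None else self.proj(x)
        return h + skip


class TCNEncoder(Module):
    """Residual TCN mapping (N, W, C) raw windows to (N, H) embeddings."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator):
        super().__init__()
        if not isinstance(spec.input_shape, tuple):
            raise ValueError("TCN encoder needs a (W, C) input shape")
        w, c = spec.input_shape
        self.spec = spec
        n_pools = spec.n_tcn_blocks // spec.pool_every
        min_w = 2 ** n_pools
        if w < min_w:
            raise ValueError(
                f"window length W={w} too small for this encoder; the "
                f"{n_pools} temporal max-pools require W >= {min_w}")
        blocks: list[Module] = []
        in_ch = c
        for i, out_ch in enumerate(spec.channels_per_block):
            blocks.append(_TCNBlock(in_ch, out_ch, spec.kernel_size,
                                    dilation=2 ** i, rng=rng))
            in_ch = out_ch
        self.blocks = blocks
        for i, blk in enumerate(blocks):
            setattr(self, f"block{i}", blk)
        self.pool = MaxPool1d(2)
        self.fc = Linear(in_ch, spec.embedding_dim, rng)

    def forward(self, x) -> Tensor:
        x = astensor(x)
        if x.ndim == 2:  # single window
            x = x.reshape(1, *x.shape)
        h = x.transpose(0, 2, 1)  # (N, C, W)
        for i, blk in enumerate(self.blocks):
            h = blk(h)
            if (i + 1) % self.spec.pool_every == 0:
                h = self.pool(h)
        h = h.mean(axis=2)  # global average pooling over time
        return self.fc(h)


class _ResidualFCBlock(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(in_dim, out_dim, rng)
        self.bn1 = BatchNorm1d(out_dim)
        self.fc2 = Linear(out_dim, out_dim, rng)
        self.bn2 = BatchNorm1d(out_dim)
        self.proj = Linear(in_dim, out_dim, rng) if in_dim != out_dim else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn1(self.fc1(x)).relu()
        h = self.bn2(self.fc2(h)).relu()
        skip = x if self.proj is None else self.proj(x)
        return h + skip


class ResidualAutoencoder(Module):
    """Residual FC encoder to H plus a plain FC decoder back to input width."""

    def __init__(self, spec: EncoderSpec, rng: np.random.Generator,
                 decoder_rng: np.random.Generator | None = None):
        super().__init__()
        if isinstance(spec.input_shape, tuple):
            raise ValueError("autoencoder expects a flat feature input size")
        in_dim = int(spec.input_shape)
        if spec.embedding_dim >= in_dim:
            warnings.warn("embedding_dim >= input width: no bottleneck",
                          stacklevel=2)
        self.spec = spec
        dims = [in_dim, *spec.hidden_dims]
        enc_blocks = [_ResidualFCBlock(dims[i], dims[i + 1], rng)
                      for i in range(len(dims) - 1)]
        self.enc_blocks = enc_blocks
        for i, blk in enumerate(enc_blocks):
            setattr(self, f"enc{i}", blk)
        self.enc_out = Linear(dims[-1], spec.embedding_dim, rng)
        drng = decoder_rng if decoder_rng is not None else rng
        dec_dims = [spec.embedding_dim, *reversed(spec.hidden_dims), in_dim]
        dec_layers = [Linear(dec_dims[i], dec_dims[i + 1], drng)
                      for i in range(len(dec_dims) - 1)]
        self.dec_layers = dec_layers
        for i, lyr in enumerate(dec_layers):
            setattr(self, f"dec{i}", lyr)

    def encode(self, x) -> Tensor:
        h = astensor(x)
        for blk in self.enc_blocks:
            h = blk(h)
        return self.enc_out(h)

    def decode(self, z: Tensor) -> Tensor:
        h = z
        for lyr in self.dec_layers[:-1]:
            h = lyr(h).relu()
        return self.dec_layers[-1](h)

    def forward(self, x) -> tuple[Tensor, Tensor]:
        z = self.encode(x)
        return z, self.decode(z)


class SiameseModel(Module):
    """Weight-shared two-branch wrapper with 1 or 2 projection heads.

    Both branch inputs run through the identical trunk; during training they
    are concatenated into one batch so batch-norm statistics mix both
    branches.
    """

    def __init__(self, trunk: Module, embedding_dim: int, heads: int,
                 seed: int):
        super().__init__()
        if heads not in (1, 2):
            raise ValueError("heads must be 1 or 2")
        self.trunk = trunk
        self.heads = heads
        self.act_head = Linear(embedding_dim, embedding_dim, _rng(seed, 2))
        self.pers_head = (Linear(embedding_dim, embedding_dim, _rng(seed, 3))
                          if heads == 2 else None)

    def _trunk_embed(self, x: Tensor) -> Tensor:
        out = self.trunk(x)
        if isinstance(out, tuple):  # autoencoder trunk: (z, recon)
            out = out[0]
        return out

    def forward(self, xa, xb):
        xa, xb = astensor(xa), astensor(xb)
        n = xa.shape[0]
        both = self._trunk_embed(concat([xa, xb], axis=0))
        za, zb = both[:n], both[n:]
        out = {"act": (self.act_head(za), self.act_head(zb))}
        if self.pers_head is not None:
            out["pers"] = (self.pers_head(za), self.pers_head(zb))
        return out

    def embed(self, x, head: str = "act") -> Tensor:
        z = self._trunk_embed(astensor(x))
        h = self.act_head if head == "act" else self.pers_head
        if h is None:
            raise ValueError("this model has no person head")
        return h(z)


@dataclass
class ModelBundle:
    """A trained (or freshly built) encoder plus its optional companions."""

    encoder: Module
    spec: EncoderSpec
    decoder_of: ResidualAutoencoder | None = None   # set when encoder is an AE
    classifier: Module | None = None                # supervised head
    siamese: SiameseModel | None = None             # weak paradigms
    paradigm: str = ""
    extras: dict = field(default_factory=dict)

    def all_modules(self) -> list[Module]:
        mods = [self.encoder]
        for m in (self.classifier, self.siamese):
            if m is not None and m not in mods:
                mods.append(m)
        return mods

    def parameters(self):
        seen: set[int] = set()
        params = []
        for m in self.all_modules():
            for p in m.parameters():
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def train(self):
        for m in self.all_modules():
            m.train()

    def eval(self):
        for m in self.all_modules():
            m.eval()

    def _apply_input_transform(self, x: np.ndarray) -> np.ndarray:
        if "scaler_mean" in self.extras:
            mean = np.asarray(self.extras["scaler_mean"], dtype=np.float64)
            std = np.asarray(self.extras["scaler_std"], dtype=np.float64)
            return (x - mean) / std
        return x

    def embed(self, x: np.ndarray, head: str = "act") -> np.ndarray:
        """Deterministic evaluation-mode embedding f(x) (for Siamese models,
        the requested head's output; otherwise the encoder output).  If the
        bundle was trained on z-scored features the stored training-set
        scaler is applied first, so callers always pass raw features."""
        self.eval()
        x = self._apply_input_transform(np.asarray(x, dtype=np.float64))
        if self.siamese is not None:
            return self.siamese.embed(x, head=head).value
        out = self.encoder(x)
        if isinstance(out, tuple):
            out = out[0]
        return out.value

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        if self.classifier is None:
            raise ValueError("bundle has no classifier head")
        self.eval()
        logits = self.classifier(self.encoder(np.asarray(x, dtype=np.float64)))
        z = logits.value - logits.value.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)


def build_tcn_encoder(spec: EncoderSpec, seed: int = 0,
                      n_classes: int | None = None) -> ModelBundle:
    """Residual TCN encoder, optionally with a linear classifier head."""
    encoder = TCNEncoder(spec, _rng(seed, 1))
    classifier = (Linear(spec.embedding_dim, n_classes, _rng(seed, 4))
                  if n_classes else None)
    return ModelBundle(encoder=encoder, spec=spec, classifier=classifier)


def build_residual_autoencoder(spec: EncoderSpec, seed: int = 0) -> ModelBundle:
    """Residual FC autoencoder on feature vectors."""
    ae = ResidualAutoencoder(spec, _rng(seed, 1), decoder_rng=_rng(seed, 5))
    return ModelBundle(encoder=ae, spec=spec, decoder_of=ae)


def build_siamese(base: ModelBundle, heads: int = 1, seed: int = 0) -> ModelBundle:
    """Wrap a bundle's encoder in a weight-shared Siamese model."""
    siam = SiameseModel(base.encoder, base.spec.embedding_dim, heads, seed)
    return ModelBundle(encoder=base.encoder, spec=base.spec,
                       decoder_of=base.decoder_of, siamese=siam,
                       paradigm=base.paradigm, extras=dict(base.extras))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_bundle(bundle: ModelBundle, directory: str | Path) -> None:
    """Save parameters (npz) with a JSON sidecar recording the EncoderSpec."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    state: dict[str, np.ndarray] = {}
    for i, m in enumerate(bundle.all_modules()):
        for k, v in m.state_dict().items():
            state[f"m{i}:{k}"] = v
    np.savez(directory / "weights.npz", **state)
    spec = asdict(bundle.spec)
    spec["input_shape"] = (list(spec["input_shape"])
                           if isinstance(spec["input_shape"], tuple)
                           else spec["input_shape"])
    meta = {"spec": spec, "paradigm": bundle.paradigm,
            "has_classifier": bundle.classifier is not None,
            "siamese_heads": bundle.siamese.heads if bundle.siamese else 0,
            "extras": {k: v for k, v in bundle.extras.items()
                       if isinstance(v, (int, float, str, bool, list))}}
    (directory / "model.json").write_text(json.dumps(meta, indent=2))


def load_bundle(directory: str | Path, n_classes: int | None = None) -> ModelBundle:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    sd = dict(meta["spec"])
    if isinstance(sd["input_shape"], list):
        sd["input_shape"] = tuple(sd["input_shape"])
    sd["channels_per_block"] = tuple(sd["channels_per_block"])
    sd["hidden_dims"] = tuple(sd["hidden_dims"])
    spec = EncoderSpec(**sd)
    if isinstance(spec.input_shape, tuple):
        bundle = build_tcn_encoder(spec, n_classes=n_classes if
                                   meta["has_classifier"] else None)
    else:
        bundle = build_residual_autoencoder(spec)
    if meta["siamese_heads"]:
        bundle = build_siamese(bundle, heads=meta["siamese_heads"])
    bundle.paradigm = meta["paradigm"]
    bundle.extras.update(meta.get("extras", {}))
    with np.load(directory / "weights.npz") as data:
        per_module: dict[int, dict[str, np.ndarray]] = {}
        for key in data.files:
            mi, name = key.split(":", 1)
            per_module.setdefault(int(mi[1:]), {})[name] = data[key]
    for i, m in enumerate(bundle.all_modules()):
        m.load_state_dict(per_module[i])
    return bundle
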