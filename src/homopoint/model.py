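"""The three-headed homologous point network.

Given a moving image M, a fixed image F, and up to L landmark coordinates X
on M, the network predicts the homologous coordinates Y on F:

1. both images are sliced into p x p patches, each patch is embedded to a
   d-vector by a small CNN and a learned position embedding is added;
2. two stacks of locality-preserving transformer encoder blocks (weights NOT
   shared between the histology and MR branches) refine the embeddings;
3. the encoded moving-image embeddings at the landmark patches are compared
   to every encoded fixed-image embedding by dot product; a row-wise softmax
   yields an L x N similarity matrix S; a soft-argmax over the patch-center
   meshgrid (range [p/2, size - p/2], spacing p) turns each row into a
   coordinate estimate, to which the landmark's offset from its own patch
   center is added.  Rows for padding landmarks are masked to (0, 0).

The head has no trainable parameters of its own: all learning lives in the
patch CNNs, position embeddings, and encoder blocks.
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path

import numpy as np

from .core import Image2D, PointSet
from .nn.autodiff import Tensor, add, gather_rows, matmul, mul, reshape, softmax, transpose
from .nn.layers import conv2x2_s2, encoder_block

__all__ = [
    "ModelConfig",
    "HomologousPointNet",
    "compute_offsets",
    "patch_index",
    "patch_centers",
    "similarity_heatmap",
    "count_parameters",
]

BRANCHES = ("histology", "mr")


@dataclasses.dataclass
class ModelConfig:
    image_size: int = 512
    patch_size: int = 16
    embed_dim: int = 128
    n_blocks: int = 6
    n_heads: int = 4
    L: int = 75
    ffn_expansion: int = 4
    use_layernorm: bool = True
    similarity_temperature: float = 1.0  # divides the dot-product logits; 1 = none

    def __post_init__(self) -> None:
        if self.image_size % self.patch_size:
            raise ValueError("image_size must be divisible by patch_size")
        if self.patch_size % 4:
            raise ValueError("patch_size must be divisible by 4 (patch CNN strides)")
        if self.embed_dim % self.n_heads:
            raise ValueError("embed_dim must be divisible by n_heads")
        if self.similarity_temperature <= 0:
            raise ValueError("similarity_temperature must be > 0")

    @property
    def grid(self) -> int:
        return self.image_size // self.patch_size

    @property
    def n_patches(self) -> int:
        return self.grid**2

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown ModelConfig keys: {sorted(unknown)}")
        return cls(**d)


def patch_centers(cfg: ModelConfig) -> np.ndarray:
    """(N, 2) patch-center meshgrid, row-major, range [p/2, size - p/2], spacing p."""
    p, g = cfg.patch_size, cfg.grid
    axis = p / 2.0 + p * np.arange(g, dtype=np.float64)
    yy, xx = np.meshgrid(axis, axis, indexing="ij")
    return np.stack([yy.ravel(), xx.ravel()], axis=1)


def patch_index(coords: np.ndarray, p: int, grid: int) -> np.ndarray:
    """Row-major flat index of the patch containing each (y, x) coordinate."""
    iy = np.floor(coords[:, 0] / p).astype(np.intp)
    ix = np.floor(coords[:, 1] / p).astype(np.intp)
    return iy * grid + ix


def compute_offsets(X: PointSet | np.ndarray, p: int) -> np.ndarray:
    """Landmark offsets from their patch centers: O = (X mod p) - floor(p/2)."""
    coords = X.coords if isinstance(X, PointSet) else np.asarray(X, dtype=np.float64)
    return np.mod(coords, p) - math.floor(p / 2)


def similarity_heatmap(S: np.ndarray, row: int, p: int, image_size: int) -> Image2D:
    """Project one row of S back into fixed-image space (Fig.-style diagnostic).

    Returns an ``image_size``-square image where each patch cell holds its
    similarity weight (constant over the cell); the underlying grid sums to 1.
    """
    S = np.asarray(S)
    if not 0 <= row < S.shape[0]:
        raise IndexError(f"row {row} out of range for similarity matrix with L={S.shape[0]}")
    g = int(round(math.sqrt(S.shape[1])))
    if g * g != S.shape[1]:
        raise ValueError("similarity matrix column count is not a perfect square")
    if g * p != image_size:
        raise ValueError("patch size inconsistent with image size")
    cell = S[row].reshape(g, g)
    return Image2D(np.clip(np.kron(cell, np.ones((p, p))), 0.0, None))


# ---------------------------------------------------------------------------
# parameter bookkeeping
# ---------------------------------------------------------------------------

def _param_shapes(cfg: ModelConfig) -> dict[str, tuple]:
    """Name -> shape for every trainable tensor (both branches)."""
    d = cfg.embed_dim
    q = cfg.patch_size // 4
    shapes: dict[str, tuple] = {}
    for br in BRANCHES:
        shapes[f"{br}/patch/w1"] = (4, 1, 64)
        shapes[f"{br}/patch/b1"] = (64,)
        shapes[f"{br}/patch/w2"] = (4, 64, 64)
        shapes[f"{br}/patch/b2"] = (64,)
        shapes[f"{br}/patch/w3"] = (q * q * 64, d)
        shapes[f"{br}/patch/b3"] = (d,)
        shapes[f"{br}/pos"] = (cfg.n_patches, d)
        for b in range(cfg.n_blocks):
            pre = f"{br}/block{b}"
            for nm in ("wq", "wk", "wv", "wo"):
                shapes[f"{pre}/{nm}"] = (d, d)
            for nm in ("bq", "bk", "bv", "bo"):
                shapes[f"{pre}/{nm}"] = (d,)
            if cfg.use_layernorm:
                shapes[f"{pre}/ln1_g"] = (d,)
                shapes[f"{pre}/ln1_b"] = (d,)
                shapes[f"{pre}/ln2_g"] = (d,)
                shapes[f"{pre}/ln2_b"] = (d,)
            e = cfg.ffn_expansion * d
            shapes[f"{pre}/w_exp"] = (d, e)
            shapes[f"{pre}/b_exp"] = (e,)
            shapes[f"{pre}/w_dw"] = (3, 3, e)
            shapes[f"{pre}/b_dw"] = (e,)
            shapes[f"{pre}/w_proj"] = (e, d)
            shapes[f"{pre}/b_proj"] = (d,)
    return shapes


def count_parameters(cfg: ModelConfig) -> int:
    """Exact trainable-parameter count for a configuration."""
    return sum(int(np.prod(s)) for s in _param_shapes(cfg).values())


class HomologousPointNet:
    """Point-correspondence network with modality-specific encoder branches."""

    def __init__(self, config: ModelConfig, seed: int | None = 0, params: dict[str, np.ndarray] | None = None):
        self.config = config
        if params is not None:
            self.params = {}
            expected = _param_shapes(config)
            if set(params) != set(expected):
                raise ValueError("parameter names do not match configuration")
            for k, v in params.items():
                v = np.asarray(v, dtype=np.float64)
                if v.shape != expected[k]:
                    raise ValueError(f"parameter {k}: shape {v.shape} != expected {expected[k]}")
                self.params[k] = Tensor(v.copy(), requires_grad=True, name=k)
        else:
            self.params = self._init_params(np.random.default_rng(seed))

    # -- parameters --------------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> dict[str, Tensor]:
        out = {}
        for name, shape in _param_shapes(self.config).items():
            leaf = name.rsplit("/", 1)[-1]
            if leaf.startswith("b") or leaf.endswith("_b"):
                data = np.zeros(shape)
            elif leaf.endswith("_g"):
                data = np.ones(shape)
            elif leaf == "pos":
                data = 0.02 * rng.standard_normal(shape)
            elif leaf in ("wo", "w_proj"):
                # near-zero residual output projections: blocks start close to
                # the identity, keeping similarity logits in a trainable range
                # (still branch-specific, so the two encoders never coincide)
                data = 1e-3 * rng.standard_normal(shape)
            elif leaf == "w_dw":
                data = rng.standard_normal(shape) / 3.0
            else:
                fan_in = int(np.prod(shape[:-1]))
                data = rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)
            out[name] = Tensor(data, requires_grad=True, name=name)
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        if set(state) != set(self.params):
            raise ValueError("state dict names do not match model parameters")
        for k, v in state.items():
            v = np.asarray(v, dtype=np.float64)
            if v.shape != self.params[k].data.shape:
                raise ValueError(f"parameter {k}: shape mismatch")
            self.params[k].data = v.copy()

    def branch_param_names(self, branch: str) -> list[str]:
        return [k for k in self.params if k.startswith(branch + "/")]

    # -- checkpointing ------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Single-file archive: all named tensors + JSON-serialized config."""
        arrays = {k.replace("/", "__"): v.data for k, v in self.params.items()}
        arrays["__config__"] = np.frombuffer(
            json.dumps(self.config.to_dict()).encode(), dtype=np.uint8
        )
        np.savez(str(path), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "HomologousPointNet":
        with np.load(str(path)) as z:
            cfg = ModelConfig.from_dict(json.loads(bytes(z["__config__"].tobytes()).decode()))
            params = {k.replace("__", "/"): z[k] for k in z.files if k != "__config__"}
        return cls(cfg, params=params)

    # -- forward graph ------------------------------------------------------
    def _as_pixels(self, img: Image2D | np.ndarray) -> np.ndarray:
        px = img.pixels if isinstance(img, Image2D) else np.asarray(img, dtype=np.float64)
        if px.shape != (self.config.image_size, self.config.image_size):
            raise ValueError(
                f"image shape {px.shape} does not match configured size {self.config.image_size}"
            )
        return px

    def embed_patches(self, img: Image2D | np.ndarray, branch: str) -> Tensor:
        """Patch CNN + learned position embedding -> (N, d) embeddings P."""
        if branch not in BRANCHES:
            raise ValueError(f"unknown branch {branch!r}")
        cfg = self.config
        px = self._as_pixels(img)
        p, g = cfg.patch_size, cfg.grid
        # row-major patch extraction: (N, p, p, 1)
        patches = px.reshape(g, p, g, p).transpose(0, 2, 1, 3).reshape(cfg.n_patches, p, p, 1)
        x = Tensor(patches)
        w = self.params
        from .nn.autodiff import gelu

        x = gelu(conv2x2_s2(x, w[f"{branch}/patch/w1"], w[f"{branch}/patch/b1"]))
        x = gelu(conv2x2_s2(x, w[f"{branch}/patch/w2"], w[f"{branch}/patch/b2"]))
        q = p // 4
        x = reshape(x, (cfg.n_patches, q * q * 64))
        x = add(matmul(x, w[f"{branch}/patch/w3"]), w[f"{branch}/patch/b3"])
        return add(x, w[f"{branch}/pos"])

    def local_vit_block(self, emb: Tensor, branch: str, block: int, **debug) -> Tensor:
        cfg = self.config
        n = emb.shape[0]
        if int(round(math.sqrt(n))) ** 2 != n:
            raise ValueError("token count must be a perfect square for spatial reshape")
        pre = f"{branch}/block{block}"
        block_params = {k.rsplit("/", 1)[-1]: v for k, v in self.params.items() if k.startswith(pre + "/")}
        return encoder_block(
            emb,
            block_params,
            cfg.n_heads,
            int(round(math.sqrt(n))),
            use_layernorm=cfg.use_layernorm,
            **debug,
        )

    def encode(self, emb: Tensor, branch: str, **debug) -> Tensor:
        """Run the branch's full encoder stack (n_blocks chained local blocks)."""
        if branch not in BRANCHES:
            raise ValueError(f"unknown branch {branch!r}")
        for b in range(self.config.n_blocks):
            emb = self.local_vit_block(emb, branch, b, **debug)
        return emb

    def gather_landmark_embeddings(self, enc_m: Tensor, X: PointSet) -> Tensor:
        """Eq.-1 gather: row i = encoding of the patch containing landmark i.

        Invalid landmarks gather patch 0 (placeholder only; the output mask
        guarantees they never influence results).
        """
        cfg = self.config
        coords = X.coords
        if np.any((coords[X.valid] < 0) | (coords[X.valid] >= cfg.image_size)):
            raise ValueError("landmark outside image bounds")
        idx = patch_index(coords, cfg.patch_size, cfg.grid)
        idx[~X.valid] = 0
        return gather_rows(enc_m, idx)

    def similarity(self, gathered: Tensor, enc_f: Tensor) -> Tensor:
        """Eq.-3 similarity: row-wise softmax of the L x N dot-product matrix."""
        if gathered.shape[1] != enc_f.shape[1]:
            raise ValueError("embedding dimensions differ between branches")
        logits = matmul(gathered, transpose(enc_f, (1, 0)))
        if self.config.similarity_temperature != 1.0:
            logits = mul(logits, Tensor(1.0 / self.config.similarity_temperature))
        return softmax(logits, axis=-1)

    def soft_argmax(self, S: Tensor) -> Tensor:
        """Expected patch-center coordinate under each similarity row."""
        return matmul(S, Tensor(patch_centers(self.config)))

    def forward(
        self,
        M: Image2D | np.ndarray,
        F: Image2D | np.ndarray,
        X: PointSet,
        moving_branch: str = "histology",
        fixed_branch: str = "mr",
    ) -> dict[str, Tensor]:
        """Full forward pass; returns the graph nodes keyed by stage."""
        cfg = self.config
        if len(X) != cfg.L:
            raise ValueError(f"X must be padded to L={cfg.L} (got {len(X)})")
        emb_m = self.embed_patches(M, moving_branch)
        emb_f = self.embed_patches(F, fixed_branch)
        enc_m = self.encode(emb_m, moving_branch)
        enc_f = self.encode(emb_f, fixed_branch)
        gathered = self.gather_landmark_embeddings(enc_m, X)
        S = self.similarity(gathered, enc_f)
        y_hat = self.soft_argmax(S)
        offsets = compute_offsets(X, cfg.patch_size)
        mask = X.valid.astype(np.float64)[:, None]
        y = mul(add(y_hat, Tensor(offsets)), Tensor(mask))
        return {"emb_m": emb_m, "emb_f": emb_f, "enc_m": enc_m, "enc_f": enc_f,
                "gathered": gathered, "S": S, "y_hat": y_hat, "offsets": offsets, "Y": y}

    def predict_points(
        self,
        M: Image2D | np.ndarray,
        F: Image2D | np.ndarray,
        X: PointSet,
        moving_branch: str = "histology",
        fixed_branch: str = "mr",
    ) -> PointSet:
        """Predict homologous fixed-frame points for the landmarks in X."""
        out = self.forward(M, F, X, moving_branch, fixed_branch)
        return PointSet(out["Y"].data.copy(), X.valid.copy())

    def similarity_matrix(self, M, F, X, moving_branch="histology", fixed_branch="mr") -> np.ndarray:
        return self.forward(M, F, X, moving_branch, fixed_branch)["S"].data.copy()
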