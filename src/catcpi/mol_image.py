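"""2D molecular depictions and the geometric robustness transforms.

A SMILES string is rendered (via RDKit's 2D drawing) to a 3 x S x S float
array in [0, 1], white background, dark ink — the raster the image branch of
the model consumes.  The robustness suite perturbs a dataset's depictions by
one of four protocols:

rotation     1/4 of compounds each rotated 90/180/270 degrees, rest unchanged
hflip/vflip  1/2 of compounds flipped, rest unchanged
translation  depiction shrunk to h x w and pushed into one of the four
             corners of the white S x S canvas, 1/4 of compounds per corner;
             the displacement is half the size difference per axis

Arrays are indexed (channel, row, col) with row 0 at top; rotation is
counter-clockwise.  For n not divisible by the group count, leftovers stay
unchanged (rotation/flips) or join the last corner (translation), so the
transformed fraction never exceeds the nominal one.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
from PIL import Image
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.Draw import rdMolDraw2D

DEFAULT_SIZE = 128  # training default; 64 and 256 used in the size sweep

ROTATION_LABELS = ("rot90", "rot180", "rot270", "identity")
FLIP_LABELS = {"hflip": ("hflip", "identity"), "vflip": ("vflip", "identity")}
CORNER_LABELS = ("top-left", "top-right", "bottom-left", "bottom-right")
METHODS = ("rotation", "hflip", "vflip", "translation")


class SmilesParseError(ValueError):
    pass


class RenderError(RuntimeError):
    pass


@dataclass(frozen=True)
class MoleculeImage:
    """3 x S x S raster of a 2D depiction, values in [0, 1], white background."""

    pixels: np.ndarray
    source_smiles: str
    size: int

    def __post_init__(self):
        s = self.size
        if self.pixels.shape != (3, s, s):
            raise ValueError(f"expected (3,{s},{s}) pixels, got {self.pixels.shape}")

    @property
    def ink_fraction(self) -> float:
        """Fraction of non-white pixels."""
        white = np.all(self.pixels >= 1.0 - 1e-6, axis=0)
        return float(1.0 - white.mean())


def render_molecule(smiles: str, size: int = DEFAULT_SIZE) -> MoleculeImage:
    """Render a SMILES to a deterministic fixed-size RGB depiction.

    Canonical 2D coordinates are computed from the molecular graph and the
    drawing options are pinned, so the same SMILES at the same size always
    yields identical pixels.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    try:
        AllChem.Compute2DCoords(mol)
        drawer = rdMolDraw2D.MolDraw2DCairo(size, size)
        opts = drawer.drawOptions()
        opts.bondLineWidth = 2
        opts.padding = 0.08
        rdMolDraw2D.PrepareAndDrawMolecule(drawer, mol)
        drawer.FinishDrawing()
        png = drawer.GetDrawingText()
    except SmilesParseError:
        raise
    except Exception as exc:  # pragma: no cover - rdkit internal failures
        raise RenderError(f"depiction failed for {smiles!r}: {exc}") from exc
    img = Image.open(io.BytesIO(png)).convert("RGB")
    arr = np.asarray(img, dtype=np.float64) / 255.0  # (S, S, 3)
    return MoleculeImage(pixels=arr.transpose(2, 0, 1), source_smiles=smiles, size=size)


@dataclass(frozen=True)
class TransformPlan:
    method: str
    assignment: tuple[str, ...]  # per-compound transform label
    seed: int
    size: tuple[int, int] | None = None  # (h, w), translation only

    def group_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.assignment:
            out[lab] = out.get(lab, 0) + 1
        return out


def plan_transform(n: int, method: str, size: tuple[int, int] | None = None,
                   seed: int = 0) -> TransformPlan:
    """Randomly assign each of n compounds a transform label.

    Rotation uses four groups (90/180/270/identity) of floor(n/4) each with
    the remainder unchanged; flips transform exactly floor(n/2); translation
    fills the four corners, remainder to the last corner.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; one of {METHODS}")
    if method == "translation" and size is None:
        raise ValueError("translation requires a (h, w) size")
    if method != "translation" and size is not None:
        raise ValueError(f"{method} takes no size argument")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    labels = np.empty(n, dtype=object)
    if method == "rotation":
        q = n // 4
        for i, lab in enumerate(ROTATION_LABELS[:3]):
            labels[perm[i * q:(i + 1) * q]] = lab
        labels[perm[3 * q:]] = "identity"
    elif method in ("hflip", "vflip"):
        q = n // 2
        labels[perm[:q]] = method
        labels[perm[q:]] = "identity"
    else:  # translation: remainder joins the last corner
        q = n // 4
        for i, lab in enumerate(CORNER_LABELS[:3]):
            labels[perm[i * q:(i + 1) * q]] = lab
        labels[perm[3 * q:]] = CORNER_LABELS[3]
    return TransformPlan(method=method, assignment=tuple(labels), seed=seed, size=size)


def _downscale(pixels: np.ndarray, h: int, w: int) -> np.ndarray:
    """Area-averaging (BOX) resample of a (3, S, S) array to (3, h, w)."""
    out = np.empty((3, h, w), dtype=pixels.dtype)
    for c in range(3):
        im = Image.fromarray(pixels[c].astype(np.float32), mode="F")
        out[c] = np.asarray(im.resize((w, h), resample=Image.Resampling.BOX))
    return np.clip(out, 0.0, 1.0)


def apply_transform(img: MoleculeImage, label: str,
                    size: tuple[int, int] | None = None) -> MoleculeImage:
    """Apply one transform label from a plan's alphabet to a rendered image."""
    px, S = img.pixels, img.size
    if label == "identity":
        out = px.copy()
    elif label == "rot90":
        out = np.rot90(px, 1, axes=(1, 2)).copy()
    elif label == "rot180":
        out = np.rot90(px, 2, axes=(1, 2)).copy()
    elif label == "rot270":
        out = np.rot90(px, 3, axes=(1, 2)).copy()
    elif label == "hflip":
        out = np.flip(px, axis=2).copy()
    elif label == "vflip":
        out = np.flip(px, axis=1).copy()
    elif label in CORNER_LABELS:
        if size is None:
            raise ValueError("corner translation requires the (h, w) size")
        h, w = size
        if h >= S or w >= S:
            raise ValueError(f"reduced size ({h},{w}) must be smaller than {S}")
        small = _downscale(px, h, w)
        out = np.ones_like(px)
        top = 0 if label.startswith("top") else S - h
        left = 0 if label.endswith("left") else S - w
        out[:, top:top + h, left:left + w] = small
    else:
        raise ValueError(f"unknown transform label {label!r}")
    return MoleculeImage(pixels=out, source_smiles=img.source_smiles, size=S)


def apply_plan(images: list[MoleculeImage], plan: TransformPlan) -> list[MoleculeImage]:
    if len(images) != len(plan.assignment):
        raise ValueError("plan length does not match image count")
    return [apply_transform(im, lab, plan.size)
            for im, lab in zip(images, plan.assignment)]


# ----------------------------------------------------------------------- I/O

def save_png(img: MoleculeImage, path) -> None:
    arr = np.clip(img.pixels * 255.0 + 0.5, 0, 255).astype(np.uint8).transpose(1, 2, 0)
    Image.fromarray(arr, mode="RGB").save(path)


def load_png(path, smiles: str = "") -> MoleculeImage:
    arr = np.asarray(Image.open(path).convert("RGB"), dtype=np.float64) / 255.0
    s = arr.shape[0]
    return MoleculeImage(pixels=arr.transpose(2, 0, 1), source_smiles=smiles, size=s)


def render_batch(smiles_list, size: int = DEFAULT_SIZE, cache: dict | None = None) -> np.ndarray:
    """Render unique SMILES once; return a (n, 3, S, S) float32 stack."""
    cache = {} if cache is None else cache
    out = np.empty((len(smiles_list), 3, size, size), dtype=np.float32)
    for i, smi in enumerate(smiles_list):
        key = (smi, size)
        if key not in cache:
            cache[key] = render_molecule(smi, size).pixels.astype(np.float32)
        out[i] = cache[key]
    return out
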