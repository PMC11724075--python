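"""Synthetic inputs with ground truth for every stage of the pipeline.

Four generators emulate the data a dimerization-agonist campaign produces:

* ``simulate_screen`` — 384-well luminescence plates with multiplicative
  row/column gradients, edge depression and multiplicative noise, plus a
  small fraction of spiked active wells whose effect is sized in robust
  residual-scale units (``spike_effect × noise_cv × grand_mean``), so
  B-score recovery targets are independent of the luminescence scale.
* ``generate_library`` — SMILES libraries assembled from a small fragment
  grammar (rings, linkers, terminal groups); actives carry an embedded
  pharmacophore core, inactives are grammar draws verified not to match it,
  and a configurable fraction of activity labels is flipped.
* ``simulate_drc`` — raw-signal dose-response tables on a 2-fold dilution
  series with positive/negative control rows, built from known 4PL
  parameters with multiplicative noise.
* ``render_cell_image`` — two-channel 16-bit micrographs (nuclei + cell
  body) of non-overlapping elliptical cells with one nucleus each and known
  pixel-exact areas; border-straddling cells can be requested.

Every generator is a pure function of its spec (including the seed): the
same spec yields byte-identical output, and each generated entity has
exactly one ground-truth record.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from rdkit import Chem
from skimage.draw import ellipse as draw_ellipse

from .doseresponse import DEFAULT_DILUTION_M, FourPLFit, four_pl
from .exceptions import DataError, LayoutError, PackingError, PatternError
from .library import CompoundLibrary
from .plates import NEG, POS, SAMPLE, PlateGrid

# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PlateLayout:
    """Rectangular plate layout with dedicated control columns.

    Default 384-well (16×24): positive controls in column 1, negative
    controls in column 22 (0-based, edge-adjacent), samples elsewhere.
    """

    n_rows: int = 16
    n_cols: int = 24
    pos_cols: tuple[int, ...] = (1,)
    neg_cols: tuple[int, ...] = (22,)

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise LayoutError("layout must be at least 2x2")
        for c in (*self.pos_cols, *self.neg_cols):
            if not 0 <= c < self.n_cols:
                raise LayoutError(f"control column {c} outside plate")
        if set(self.pos_cols) & set(self.neg_cols):
            raise LayoutError("a column cannot hold both control roles")

    @property
    def wells(self) -> int:
        return self.n_rows * self.n_cols

    def roles(self) -> np.ndarray:
        roles = np.full((self.n_rows, self.n_cols), SAMPLE, dtype=object)
        for c in self.pos_cols:
            roles[:, c] = POS
        for c in self.neg_cols:
            roles[:, c] = NEG
        return roles


@dataclass(frozen=True)
class PlateEffectSpec:
    """Generative model of one screening campaign's plate artifacts.

    ``row_gradient``/``col_gradient`` are the fractional signal change at
    the plate extremes (0.3 → the factor runs from −30% to +30% across the
    plate); ``edge_depression`` multiplies outermost-ring wells by
    ``1 − edge_depression``; noise is multiplicative ``1 + N(0, noise_cv)``.
    Active wells get an additive spike of ``spike_effect × noise_cv ×
    grand_mean`` (i.e. ``spike_effect`` robust residual-scale units).
    """

    grand_mean: float = 1.0e6
    row_gradient: float = 0.3
    col_gradient: float = -0.3
    edge_depression: float = 0.2
    noise_cv: float = 0.05
    spike_rate: float = 0.02
    spike_effect: float = 8.0
    pos_level: float = 2.0
    neg_level: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grand_mean <= 0:
            raise DataError("grand_mean must be positive")
        if self.noise_cv < 0:
            raise DataError("noise_cv must be >= 0")
        if not 0.0 <= self.spike_rate <= 1.0:
            raise DataError("spike_rate must lie in [0, 1]")


@dataclass(frozen=True)
class LibrarySpec:
    """Planted-pharmacophore compound library.

    ``pharmacophore`` is a SMILES fragment used both as the graft core of
    active compounds and as the substructure query defining truth.
    """

    n_compounds: int = 2000
    pharmacophore: str = "O=C(Nc1ccccc1)"
    active_fraction: float = 0.1
    label_noise: float = 0.0
    seed: int = 0
    id_prefix: str = "LIB"

    def __post_init__(self) -> None:
        if not 0.0 <= self.active_fraction <= 1.0:
            raise DataError("active_fraction must lie in [0, 1]")
        if not 0.0 <= self.label_noise <= 1.0:
            raise DataError("label_noise must lie in [0, 1]")
        if Chem.MolFromSmiles(self.pharmacophore) is None:
            raise PatternError(f"pharmacophore {self.pharmacophore!r} does not parse")


@dataclass(frozen=True)
class CellImageSpec:
    """Two-channel synthetic micrograph of nucleated cells.

    16-bit single plane per channel; additive Gaussian noise clipped to the
    dtype range.  Cells are placed without overlap (with a small gap) unless
    ``allow_overlap``; ``n_border_cells`` of them straddle the image border
    to exercise border removal.
    """

    image_shape: tuple[int, int] = (768, 768)
    n_cells: int = 12
    cell_area_range: tuple[float, float] = (2000.0, 20000.0)
    nucleus_area_range: tuple[float, float] = (600.0, 1400.0)
    cell_intensity: float = 3000.0
    nucleus_intensity: float = 6000.0
    background_intensity: float = 100.0
    noise_sd: float = 50.0
    bit_depth: int = 16
    allow_overlap: bool = False
    n_border_cells: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_shape) < 64:
            raise DataError("image must be at least 64x64")
        if self.cell_area_range[0] <= 0 or self.nucleus_area_range[0] <= 0:
            raise DataError("areas must be positive")
        top = 2**self.bit_depth - 1
        for v in (self.cell_intensity, self.nucleus_intensity, self.background_intensity):
            if not 0 <= v <= top:
                raise DataError("intensities must fit the declared bit depth")
        if self.n_border_cells > self.n_cells:
            raise DataError("n_border_cells cannot exceed n_cells")


@dataclass
class GroundTruth:
    """Truth records for generated data; each generator fills its slice.

    ``wells`` — per-well active flags and expected means;
    ``compounds`` — per-compound carrier truth and (noisy) labels;
    ``curves`` — true 4PL parameters per compound;
    ``cells`` — per-cell pixel areas; ``cell_labels``/``nucleus_labels`` —
    truth label images.
    """

    wells: pd.DataFrame | None = None
    compounds: pd.DataFrame | None = None
    curves: dict[str, FourPLFit] = field(default_factory=dict)
    cells: pd.DataFrame | None = None
    cell_labels: np.ndarray | None = None
    nucleus_labels: np.ndarray | None = None


# --------------------------------------------------------------------------
# plates
# --------------------------------------------------------------------------


def expected_well_mean(spec: PlateEffectSpec, layout: PlateLayout, i: int, j: int) -> float:
    """Noise-free expected signal of sample well (i, j) under the spec."""
    u = 2.0 * i / (layout.n_rows - 1) - 1.0
    v = 2.0 * j / (layout.n_cols - 1) - 1.0
    value = spec.grand_mean * (1.0 + spec.row_gradient * u) * (1.0 + spec.col_gradient * v)
    if i in (0, layout.n_rows - 1) or j in (0, layout.n_cols - 1):
        value *= 1.0 - spec.edge_depression
    return value


def simulate_screen(
    spec: PlateEffectSpec,
    n_plates: int = 10,
    layout: PlateLayout | None = None,
) -> tuple[list[PlateGrid], GroundTruth]:
    """Simulate a primary screen: plates of raw signal plus per-well truth."""
    layout = layout or PlateLayout()
    rng = np.random.default_rng(spec.seed)
    roles = layout.roles()
    sample_mask = roles == SAMPLE
    spike_amp = spec.spike_effect * spec.noise_cv * spec.grand_mean

    plates: list[PlateGrid] = []
    truth_rows = []
    counter = 0
    for p in range(n_plates):
        plate_id = f"P{p + 1:03d}"
        base = np.empty((layout.n_rows, layout.n_cols))
        for i in range(layout.n_rows):
            for j in range(layout.n_cols):
                base[i, j] = expected_well_mean(spec, layout, i, j)
        base[roles == POS] = spec.pos_level * spec.grand_mean
        base[roles == NEG] = spec.neg_level * spec.grand_mean

        active = np.zeros_like(sample_mask)
        active[sample_mask] = rng.random(sample_mask.sum()) < spec.spike_rate
        noise = 1.0 + rng.normal(0.0, spec.noise_cv, size=base.shape) if spec.noise_cv > 0 else 1.0
        values = base * noise + np.where(active, spike_amp, 0.0)
        values = np.clip(values, 0.0, None)

        ids = np.full(base.shape, "", dtype=object)
        for i, j in zip(*np.nonzero(sample_mask)):
            ids[i, j] = f"CMP-{counter:05d}"
            counter += 1
        plates.append(PlateGrid(plate_id, values, roles.copy(), ids))
        for i, j in zip(*np.nonzero(sample_mask)):
            truth_rows.append(
                {
                    "plate_id": plate_id,
                    "row": int(i),
                    "col": int(j),
                    "compound_id": ids[i, j],
                    "is_active": bool(active[i, j]),
                    "expected_mean": base[i, j],
                    "spike_amplitude": spike_amp if active[i, j] else 0.0,
                }
            )
    truth = GroundTruth(wells=pd.DataFrame(truth_rows))
    return plates, truth


# --------------------------------------------------------------------------
# libraries
# --------------------------------------------------------------------------

_RINGS = (
    "c1ccccc1",
    "c1ccncc1",
    "c1ccsc1",
    "c1ccco1",
    "C1CCCCC1",
    "C1CCNCC1",
    "C1CCOCC1",
    "C1CCCC1",
)
_LINKERS = ("", "C", "CC", "CCC", "OC", "NC", "CS", "C(C)")
#: written head-last so they can precede a ring atom in a SMILES string
_PREFIXES = ("", "C", "CC", "CCC", "OC", "CS", "NC")
_TERMINALS = (
    "C",
    "O",
    "N",
    "F",
    "Cl",
    "Br",
    "C#N",
    "C(F)(F)F",
    "OC",
    "N(C)C",
    "C(C)C",
    "CO",
    "CCO",
)


def _random_tail(rng: np.random.Generator) -> str:
    link = _LINKERS[rng.integers(len(_LINKERS))]
    if rng.random() < 0.4:
        return link + _RINGS[rng.integers(len(_RINGS))]
    return link + _TERMINALS[rng.integers(len(_TERMINALS))]


def _random_inactive(rng: np.random.Generator, query: Chem.Mol) -> str:
    for _ in range(200):
        prefix = _PREFIXES[rng.integers(len(_PREFIXES))]
        smiles = prefix + _RINGS[rng.integers(len(_RINGS))] + _random_tail(rng)
        if rng.random() < 0.5:
            smiles += _random_tail(rng)
        mol = Chem.MolFromSmiles(smiles)
        if mol is not None and not mol.HasSubstructMatch(query):
            return Chem.MolToSmiles(mol)
    raise PatternError("grammar cannot avoid the pharmacophore; pattern too permissive")


def _random_active(rng: np.random.Generator, core: str, query: Chem.Mol) -> str:
    for _ in range(200):
        smiles = core + _random_tail(rng)
        if rng.random() < 0.5:
            smiles += _random_tail(rng)
        mol = Chem.MolFromSmiles(smiles)
        if mol is not None and mol.HasSubstructMatch(query):
            return Chem.MolToSmiles(mol)
    # the bare core always matches itself
    return Chem.MolToSmiles(Chem.MolFromSmiles(core))


def generate_library(spec: LibrarySpec) -> tuple[CompoundLibrary, GroundTruth]:
    """Generate a library whose activity is carrying the pharmacophore.

    A compound is truly active iff it contains ``spec.pharmacophore`` as a
    substructure; the observed ``label`` column then has ``label_noise`` of
    the labels flipped.  Libraries round-trip through ``.smi``.
    """
    rng = np.random.default_rng(spec.seed)
    query = Chem.MolFromSmiles(spec.pharmacophore)
    rows = []
    for idx in range(spec.n_compounds):
        carrier = bool(rng.random() < spec.active_fraction)
        smiles = (
            _random_active(rng, spec.pharmacophore, query)
            if carrier
            else _random_inactive(rng, query)
        )
        flipped = bool(rng.random() < spec.label_noise)
        rows.append(
            {
                "compound_id": f"{spec.id_prefix}-{idx:05d}",
                "smiles": smiles,
                "is_carrier": carrier,
                "label": int(carrier != flipped),
            }
        )
    truth_df = pd.DataFrame(rows)
    lib = CompoundLibrary(
        truth_df[["compound_id", "smiles", "label"]].copy(), provenance="candidate"
    )
    return lib, GroundTruth(compounds=truth_df)


# --------------------------------------------------------------------------
# dose-response
# --------------------------------------------------------------------------


def simulate_drc(
    true_fit: FourPLFit,
    concentrations: Sequence[float] = DEFAULT_DILUTION_M,
    n_reps: int = 4,
    noise_cv: float = 0.05,
    seed: int = 0,
    compound_id: str = "CMP-TEST",
    pos_level: float = 1.0e6,
    neg_level: float = 1.0e5,
    n_control_reps: int = 8,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Raw-signal dose-response table from known 4PL parameters.

    The true curve lives on the %-of-reference scale; raw signals are
    ``neg + (pos − neg) × y/100`` with multiplicative ``1 + N(0, noise_cv)``
    noise, and control rows at ``pos_level``/``neg_level`` (noisy too) are
    appended so normalization can be exercised end to end.
    """
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise DataError("concentrations must be strictly positive")
    rng = np.random.default_rng(seed)
    rows = []
    for c in conc:
        y_pct = float(four_pl(c, true_fit.bottom, true_fit.top, true_fit.ec50, true_fit.hill))
        raw = neg_level + (pos_level - neg_level) * y_pct / 100.0
        for rep in range(n_reps):
            noise = 1.0 + rng.normal(0.0, noise_cv) if noise_cv > 0 else 1.0
            rows.append(
                {
                    "compound_id": compound_id,
                    "conc_molar": c,
                    "replicate": rep,
                    "value": raw * noise,
                    "role": "sample",
                }
            )
    for role, level in (("pos", pos_level), ("neg", neg_level)):
        for rep in range(n_control_reps):
            noise = 1.0 + rng.normal(0.0, noise_cv) if noise_cv > 0 else 1.0
            rows.append(
                {
                    "compound_id": role.upper(),
                    "conc_molar": np.nan,
                    "replicate": rep,
                    "value": level * noise,
                    "role": role,
                }
            )
    table = pd.DataFrame(rows, columns=["compound_id", "conc_molar", "replicate", "value", "role"])
    return table, GroundTruth(curves={compound_id: true_fit})


# --------------------------------------------------------------------------
# images
# --------------------------------------------------------------------------


def render_cell_image(spec: CellImageSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a two-channel image (channel 0 nuclei, channel 1 cell body).

    Cells are ellipses with one centered circular nucleus; truth records the
    exact rasterized pixel area of every cell and nucleus and whether the
    cell touches the border.  Raises :class:`PackingError` when the
    requested cells cannot be placed without overlap.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    cell_ch = np.full((h, w), spec.background_intensity, dtype=float)
    nuc_ch = np.full((h, w), spec.background_intensity, dtype=float)
    cell_labels = np.zeros((h, w), dtype=np.int32)
    nucleus_labels = np.zeros((h, w), dtype=np.int32)

    gap = 3.0
    placed: list[tuple[float, float, float]] = []  # (r, c, bounding radius)
    truth_rows = []
    for cell_id in range(1, spec.n_cells + 1):
        on_border = cell_id <= spec.n_border_cells
        area = rng.uniform(*spec.cell_area_range)
        aspect = rng.uniform(0.6, 1.0)
        r_rad = float(np.sqrt(area / (np.pi * aspect)))
        c_rad = aspect * r_rad
        rot = rng.uniform(0.0, np.pi)
        rmax = max(r_rad, c_rad)

        ok = False
        for _ in range(500):
            if on_border:
                side = rng.integers(4)
                t = rng.uniform(0.15, 0.85)
                half = 0.5 * rmax
                if side == 0:
                    cr, cc = -half, t * w
                elif side == 1:
                    cr, cc = h - 1 + half, t * w
                elif side == 2:
                    cr, cc = t * h, -half
                else:
                    cr, cc = t * h, w - 1 + half
            else:
                if h - 2 * (rmax + 2) <= 0 or w - 2 * (rmax + 2) <= 0:
                    raise PackingError("cell larger than image")
                cr = rng.uniform(rmax + 2, h - 1 - rmax - 2)
                cc = rng.uniform(rmax + 2, w - 1 - rmax - 2)
            if spec.allow_overlap or all(
                np.hypot(cr - pr, cc - pc) > rmax + prad + gap for pr, pc, prad in placed
            ):
                ok = True
                break
        if not ok:
            raise PackingError(
                f"could not place cell {cell_id} of {spec.n_cells} in {spec.image_shape}"
            )
        placed.append((cr, cc, rmax))

        rr, cc_px = draw_ellipse(cr, cc, r_rad, c_rad, shape=(h, w), rotation=rot)
        cell_ch[rr, cc_px] = spec.cell_intensity
        cell_labels[rr, cc_px] = cell_id
        cell_area_px = int(rr.size)

        nuc_area = rng.uniform(*spec.nucleus_area_range)
        nuc_rad = min(float(np.sqrt(nuc_area / np.pi)), 0.8 * min(r_rad, c_rad))
        nr_c = np.clip(cr, 0, h - 1)
        nc_c = np.clip(cc, 0, w - 1)
        nrr, ncc = draw_ellipse(nr_c, nc_c, nuc_rad, nuc_rad, shape=(h, w))
        nuc_ch[nrr, ncc] = spec.nucleus_intensity
        nucleus_labels[nrr, ncc] = cell_id
        touches = bool(
            rr.size
            and (rr.min() == 0 or rr.max() == h - 1 or cc_px.min() == 0 or cc_px.max() == w - 1)
        )
        truth_rows.append(
            {
                "cell_id": cell_id,
                "center_row": float(cr),
                "center_col": float(cc),
                "area_px": cell_area_px,
                "nucleus_area_px": int(nrr.size),
                "touches_border": touches,
            }
        )

    top = float(2**spec.bit_depth - 1)
    image = np.stack([nuc_ch, cell_ch])
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    image = np.clip(np.rint(image), 0, top).astype(np.uint16 if spec.bit_depth <= 16 else np.uint32)
    truth = GroundTruth(
        cells=pd.DataFrame(
            truth_rows,
            columns=[
                "cell_id",
                "center_row",
                "center_col",
                "area_px",
                "nucleus_area_px",
                "touches_border",
            ],
        ),
        cell_labels=cell_labels,
        nucleus_labels=nucleus_labels,
    )
    return image, truth


# --------------------------------------------------------------------------
# fixtures on disk
# --------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixtures(
    outdir: str | Path,
    seed: int = 0,
    n_plates: int = 2,
    n_images: int = 2,
    plate_spec: PlateEffectSpec | None = None,
    library_spec: LibrarySpec | None = None,
    image_spec: CellImageSpec | None = None,
    true_fit: FourPLFit | None = None,
) -> dict:
    """Write one fixture of each input kind plus a JSON truth manifest.

    Emits plate CSV, ``.smi`` library, dose-response CSV and two-channel
    TIFFs (with truth label TIFFs), then a ``truth.json`` manifest listing
    every file with its SHA-256 checksum and the ground-truth records.
    Identical seeds reproduce identical checksums.
    """
    from .io import write_plates_csv  # local import to avoid a cycle

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    plate_spec = plate_spec or PlateEffectSpec(seed=seed)
    library_spec = library_spec or LibrarySpec(n_compounds=200, seed=seed + 1)
    image_spec = image_spec or CellImageSpec(seed=seed + 2)
    true_fit = true_fit or FourPLFit(bottom=0.0, top=30.0, ec50=1.05e-5, hill=1.0)

    manifest: dict = {"seed": seed, "files": {}, "truth": {}}

    plates, screen_truth = simulate_screen(plate_spec, n_plates=n_plates)
    plate_path = out / "plates.csv"
    write_plates_csv(plates, plate_path)
    manifest["truth"]["wells"] = screen_truth.wells.to_dict(orient="records")

    lib, lib_truth = generate_library(library_spec)
    smi_path = out / "library.smi"
    lib.to_smi(smi_path)
    manifest["truth"]["compounds"] = lib_truth.compounds.to_dict(orient="records")

    drc, drc_truth = simulate_drc(true_fit, seed=seed + 3)
    drc_path = out / "drc.csv"
    drc.to_csv(drc_path, index=False)
    manifest["truth"]["curves"] = {
        cid: {"bottom": f.bottom, "top": f.top, "ec50": f.ec50, "hill": f.hill}
        for cid, f in drc_truth.curves.items()
    }

    image_paths = []
    manifest["truth"]["images"] = []
    for k in range(n_images):
        ispec = CellImageSpec(**{**asdict(image_spec), "seed": image_spec.seed + k})
        image, itruth = render_cell_image(ispec)
        ipath = out / f"image_{k:03d}.tif"
        lpath = out / f"image_{k:03d}_labels.tif"
        tifffile.imwrite(ipath, image)
        tifffile.imwrite(lpath, itruth.cell_labels.astype(np.uint16))
        image_paths += [ipath, lpath]
        manifest["truth"]["images"].append(
            {"file": ipath.name, "cells": itruth.cells.to_dict(orient="records")}
        )

    for path in [plate_path, smi_path, drc_path, *image_paths]:
        manifest["files"][path.name] = _sha256(path)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not serializable: {type(o)}")

    (out / "truth.json").write_text(json.dumps(manifest, indent=2, default=_default, sort_keys=True))
    return manifest
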