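"""Synthetic two-channel fluorescence images with known ground truth.

Channel 1 emulates a DNA stain (filled elliptical nuclei, one per cell,
non-overlapping); channel 2 emulates an immunostained protein whose
integrated per-cell signal is split between nucleus and cytoplasm so
that the expected in-nucleus share equals ``nuclear_fraction_true``.
Anisotropic Gaussian foci (granule stand-ins) are planted in the
cytoplasm only, outside a 2-px dilation of the nucleus.  Poisson shot
noise and additive Gaussian read noise are applied last.

The diffuse nuclear and cytoplasmic budgets are reduced by the
actually-rendered focus mass inside the nucleus and the rest of the
soma respectively, so the planted in-soma nuclear share is exact in
expectation even when focus tails cross the nuclear boundary; focus
centers keep one major-axis sigma clear of the soma edge so only a
negligible tail mass leaves the cell.

Cells are laid out as a nucleus ellipse inside a slightly larger soma
ellipse (a thin cytoplasmic rim), which is the geometry of a neuronal
soma in a single confocal slice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["ImageSimParams", "ImageTruth", "FocusTruth", "simulate_cell_image"]

_NUCLEUS_CLEARANCE_PX = 2  # foci must sit outside this dilation of the nucleus


@dataclass(frozen=True)
class ImageSimParams:
    """Parameters of one simulated field of view.

    ``focus_elongation`` is the major/minor sigma ratio of planted foci
    (1 = round "canonical" granule, >1 = oblong "chronic" granule); the
    sigma product is preserved so focus mass does not change with shape.
    ``cell_signal_total`` is the expected integrated protein signal per
    cell before noise (counts).
    """

    width_px: int = 384
    height_px: int = 384
    n_cells: int = 4
    nuclear_fraction_true: float = 0.5
    n_foci_per_cell: int = 3
    focus_sigma_px: float = 2.5
    focus_elongation: float = 1.0
    focus_amplitude: float = 700.0
    background_level: float = 100.0
    read_noise_sd: float = 3.0
    seed: int = 0
    cell_signal_total: float = 400_000.0
    nucleus_radius_px: float = 16.0
    cytoplasm_rim_px: float = 9.0

    def validate(self) -> None:
        if not (0.0 <= self.nuclear_fraction_true <= 1.0):
            raise ValueError("nuclear_fraction_true must be in [0,1]")
        if min(self.width_px, self.height_px, self.n_cells) < 1:
            raise ValueError("image extents and n_cells must be positive")
        if self.n_foci_per_cell < 0:
            raise ValueError("n_foci_per_cell must be non-negative")
        if self.focus_sigma_px <= 0:
            raise ValueError("focus_sigma_px must be > 0")
        if self.focus_elongation < 1.0:
            raise ValueError("focus_elongation must be >= 1")
        if self.focus_amplitude <= 0:
            raise ValueError("focus_amplitude must be > 0")
        if self.background_level < 0 or self.read_noise_sd < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.cell_signal_total <= 0:
            raise ValueError("cell_signal_total must be > 0")


@dataclass(frozen=True)
class FocusTruth:
    cell: int
    row: float
    col: float
    sigma_major_px: float
    sigma_minor_px: float
    orientation_rad: float
    elongation: float


@dataclass
class ImageTruth:
    """Planted ground truth for one simulated field."""

    nuclear_labels: np.ndarray
    cell_labels: np.ndarray
    nuclear_fraction_true: np.ndarray  # per cell
    foci: list[FocusTruth] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        """JSON-serializable truth (masks excluded; write those as TIFF)."""
        return {
            "n_cells": int(self.nuclear_fraction_true.size),
            "nuclear_fraction_true": self.nuclear_fraction_true.tolist(),
            "foci": [asdict(f) for f in self.foci],
        }


def _ellipse_mask(
    shape: tuple[int, int], center: tuple[float, float],
    radii: tuple[float, float], angle: float,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr, dc = rr - center[0], cc - center[1]
    ca, sa = math.cos(angle), math.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0


def _place_cells(params: ImageSimParams, rng_parents: list[np.random.Generator]):
    """Non-overlapping cell centers with per-cell geometry.

    Placement for cell k depends only on cells < k and stream k, so a
    larger ``n_cells`` never perturbs earlier cells.
    """
    h, w = params.height_px, params.width_px
    margin = params.nucleus_radius_px + params.cytoplasm_rim_px + 4
    if 2 * margin >= min(h, w):
        raise ValueError("image too small for the configured cell size")
    placed: list[tuple[float, float, float]] = []  # row, col, outer radius
    cells = []
    for k in range(params.n_cells):
        rng = rng_parents[k]
        # mild per-cell variation in nucleus size and orientation
        nuc_r = params.nucleus_radius_px * rng.uniform(0.9, 1.1)
        aspect = rng.uniform(0.75, 0.95)
        angle = rng.uniform(0, math.pi)
        outer = nuc_r + params.cytoplasm_rim_px
        for attempt in range(200):
            r = rng.uniform(margin, h - margin)
            c = rng.uniform(margin, w - margin)
            if all(
                math.hypot(r - pr, c - pc) > outer + po + 2
                for pr, pc, po in placed
            ):
                break
        else:
            raise RuntimeError(
                f"could not place cell {k} without overlap after 200 attempts"
            )
        placed.append((r, c, outer))
        cells.append(
            {
                "center": (r, c),
                "nuc_radii": (nuc_r, nuc_r * aspect),
                "outer_radii": (outer, outer * aspect),
                "angle": angle,
            }
        )
    return cells


def simulate_cell_image(
    params: ImageSimParams,
) -> tuple[np.ndarray, ImageTruth]:
    """Render one field: (2, H, W) uint16 stack plus ground truth.

    Page 0 is the nuclear stain, page 1 the protein channel.  Identical
    parameters (including seed) give bit-identical output.
    """
    params.validate()
    shape = (params.height_px, params.width_px)
    streams = np.random.SeedSequence(params.seed).spawn(params.n_cells + 1)
    cell_rngs = [np.random.default_rng(s) for s in streams[: params.n_cells]]
    noise_rng = np.random.default_rng(streams[-1])

    cells = _place_cells(params, cell_rngs)

    nuclear_labels = np.zeros(shape, dtype=np.int32)
    cell_labels = np.zeros(shape, dtype=np.int32)
    nuclear_signal = np.zeros(shape)
    protein = np.zeros(shape)
    foci_truth: list[FocusTruth] = []
    f = params.nuclear_fraction_true

    for k, cell in enumerate(cells, start=1):
        rng = cell_rngs[k - 1]
        nuc = _ellipse_mask(shape, cell["center"], cell["nuc_radii"], cell["angle"])
        soma = _ellipse_mask(shape, cell["center"], cell["outer_radii"], cell["angle"])
        nuclear_labels[nuc] = k
        cell_labels[soma] = k
        nuclear_signal[nuc] += 800.0  # bright DNA stain, flat within nucleus

        cyto = soma & ~nuc
        n_nuc_px = int(nuc.sum())
        n_cyto_px = int(cyto.sum())
        if n_nuc_px == 0 or n_cyto_px == 0:
            raise RuntimeError(f"degenerate geometry for cell {k}")

        # -- plant foci in the cytoplasm, clear of the nucleus ----------
        clearance = _ellipse_mask(
            shape,
            cell["center"],
            (
                cell["nuc_radii"][0] + _NUCLEUS_CLEARANCE_PX,
                cell["nuc_radii"][1] + _NUCLEUS_CLEARANCE_PX,
            ),
            cell["angle"],
        )
        focus_field = np.zeros(shape)
        s_maj = params.focus_sigma_px * math.sqrt(params.focus_elongation)
        s_min = params.focus_sigma_px / math.sqrt(params.focus_elongation)
        # keep focus mass inside the soma: centers >= 2 sigma from its edge
        edge_margin = 1.0 * s_maj
        inner_soma = _ellipse_mask(
            shape,
            cell["center"],
            (
                max(cell["outer_radii"][0] - edge_margin, 1.0),
                max(cell["outer_radii"][1] - edge_margin, 1.0),
            ),
            cell["angle"],
        )
        allowed = cyto & ~clearance & inner_soma
        allowed_idx = np.flatnonzero(allowed)
        if params.n_foci_per_cell > 0 and allowed_idx.size == 0:
            raise RuntimeError(f"no cytoplasmic room for foci in cell {k}")
        min_sep = 5.0 * s_maj  # keep planted foci resolvable: unambiguous truth
        placed_foci: list[tuple[int, int]] = []
        for _ in range(params.n_foci_per_cell):
            for _attempt in range(200):
                flat = int(rng.choice(allowed_idx))
                fr, fc = divmod(flat, shape[1])
                if all(
                    math.hypot(fr - pr, fc - pc) >= min_sep for pr, pc in placed_foci
                ):
                    break
            else:
                raise RuntimeError(
                    f"could not place {params.n_foci_per_cell} separated foci "
                    f"in cell {k}; enlarge the cell or lower n_foci_per_cell"
                )
            placed_foci.append((fr, fc))
            theta = rng.uniform(0, math.pi)
            half = int(math.ceil(4 * s_maj))
            r0, r1 = max(0, fr - half), min(shape[0], fr + half + 1)
            c0, c1 = max(0, fc - half), min(shape[1], fc + half + 1)
            rr, cc = np.mgrid[r0:r1, c0:c1]
            dr, dc = rr - fr, cc - fc
            ca, sa = math.cos(theta), math.sin(theta)
            u = dr * ca + dc * sa
            v = -dr * sa + dc * ca
            focus_field[r0:r1, c0:c1] += params.focus_amplitude * np.exp(
                -0.5 * ((u / s_maj) ** 2 + (v / s_min) ** 2)
            )
            foci_truth.append(
                FocusTruth(
                    cell=k,
                    row=float(fr),
                    col=float(fc),
                    sigma_major_px=s_maj,
                    sigma_minor_px=s_min,
                    orientation_rad=theta,
                    elongation=params.focus_elongation,
                )
            )

        # -- split the per-cell budget so the in-soma nuclear share is exact
        focus_in_nuc = float(focus_field[nuc].sum())
        focus_in_cyto = float(focus_field[soma].sum()) - focus_in_nuc
        nuc_budget = f * params.cell_signal_total - focus_in_nuc
        cyto_budget = (1.0 - f) * params.cell_signal_total - focus_in_cyto
        if nuc_budget < 0 or cyto_budget < 0:
            raise ValueError(
                f"cell {k}: planted focus mass exceeds the "
                "nuclear/cytoplasmic signal budget; lower focus_amplitude "
                "or n_foci_per_cell, or raise cell_signal_total"
            )
        protein[nuc] += nuc_budget / n_nuc_px
        protein[cyto] += cyto_budget / n_cyto_px
        protein += focus_field

    truth = ImageTruth(
        nuclear_labels=nuclear_labels,
        cell_labels=cell_labels,
        nuclear_fraction_true=np.full(params.n_cells, f),
        foci=foci_truth,
    )

    stack = np.stack([nuclear_signal, protein])
    stack = stack + params.background_level
    noisy = noise_rng.poisson(stack).astype(float)
    if params.read_noise_sd > 0:
        noisy += noise_rng.normal(0.0, params.read_noise_sd, size=noisy.shape)
    image = np.clip(np.rint(noisy), 0, 65535).astype(np.uint16)
    return image, truth
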