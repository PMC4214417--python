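"""Procedural test-data generators with exact ground truth.

Everything downstream is testable without external data: rendered plants
(green strokes on a uniform background, with the composite mask recorded
at draw time), grain scatter scenes (bright ellipses with known axes and
touching pairs), and genotype/phenotype simulations with block LD,
population structure and stated heritability.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlantSceneTruth",
    "GrainSceneTruth",
    "SimPopulation",
    "render_plant",
    "render_grains",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_feature_trait_table",
]


@dataclasses.dataclass
class PlantSceneTruth:
    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray  # H x W bool, recorded at draw time
    area_px: int
    height_px: int
    n_leaves: int
    leaf_areas_px: list[int]  # per-leaf pre-overlap areas
    stem_area_px: int


@dataclasses.dataclass
class GrainSceneTruth:
    image: np.ndarray  # H x W uint8
    count: int
    semi_axes: list[tuple[float, float]]
    orientations: list[float]
    centroids: list[tuple[float, float]]
    touching_pairs: int
    masks: list[np.ndarray] | None = None


@dataclasses.dataclass
class SimPopulation:
    genotypes: "np.ndarray"  # placeholder for typing; see .matrix
    matrix: "object"  # GenotypeMatrix
    subpop: np.ndarray
    causal_idx: np.ndarray
    causal_beta: np.ndarray
    h2_causal: float
    h2_polygenic: float
    seed: int


# ---------------------------------------------------------------------------
# Plant renderer
# ---------------------------------------------------------------------------

def _stamp_disc(mask: np.ndarray, r: float, c: float, radius: int) -> None:
    h, w = mask.shape
    r0, r1 = max(0, int(r - radius)), min(h, int(r + radius + 1))
    c0, c1 = max(0, int(c - radius)), min(w, int(c + radius + 1))
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (yy - r) ** 2 + (xx - c) ** 2 <= radius**2


def render_plant(
    n_leaves: int = 6,
    stem_height_px: int = 220,
    leaf_thickness_px: int = 3,
    canvas: tuple[int, int] = (320, 320),
    background: tuple[int, int, int] = (255, 255, 255),
    seed: int = 0,
) -> PlantSceneTruth:
    """Draw a stem plus arc-stroke leaves; record the exact composite mask.

    The stem is a vertical rectangle; each leaf is a quadratic arc stamped
    with a disc brush.  Per-leaf areas are measured before compositing so
    overlap accounting is exact.
    """
    if stem_height_px < 1 or leaf_thickness_px < 1 or n_leaves < 0:
        raise ValueError("parameters must be positive")
    h, w = canvas
    if stem_height_px > h - 20:
        raise ValueError("stem exceeds canvas")
    rng = np.random.default_rng(seed)

    mask = np.zeros((h, w), dtype=bool)
    base_row = h - 10
    top_row = base_row - stem_height_px + 1
    stem_w = max(2, leaf_thickness_px)
    c0 = w // 2 - stem_w // 2
    mask[top_row : base_row + 1, c0 : c0 + stem_w] = True
    stem_area = int(mask.sum())

    leaf_areas = []
    for _ in range(n_leaves):
        leaf = np.zeros_like(mask)
        attach = rng.uniform(0.15, 0.9)
        r_start = base_row - attach * stem_height_px
        c_start = w / 2.0
        side = rng.choice((-1.0, 1.0))
        length = rng.uniform(0.25, 0.55) * min(h, w)
        droop = rng.uniform(0.2, 1.2)
        n_steps = int(length * 2)
        t = np.linspace(0.0, 1.0, n_steps)
        cc = c_start + side * length * t
        rr = r_start - length * 0.7 * t + droop * length * 0.7 * t**2
        radius = max(1, leaf_thickness_px // 2 + 1)
        for r_pt, c_pt in zip(rr, cc):
            if 0 <= r_pt < h and 0 <= c_pt < w:
                _stamp_disc(leaf, r_pt, c_pt, radius)
        leaf_areas.append(int(leaf.sum()))
        mask |= leaf

    image = np.empty((h, w, 3), dtype=np.uint8)
    image[..., 0] = background[0]
    image[..., 1] = background[1]
    image[..., 2] = background[2]
    # plant-green hues with mild per-pixel variation
    n_fg = int(mask.sum())
    g = rng.integers(140, 200, size=n_fg)
    image[..., 0][mask] = (g * 0.35).astype(np.uint8)
    image[..., 1][mask] = g.astype(np.uint8)
    image[..., 2][mask] = (g * 0.30).astype(np.uint8)

    rows = np.nonzero(mask.any(axis=1))[0]
    height_px = int(rows[-1] - rows[0] + 1)
    return PlantSceneTruth(
        image=image,
        mask=mask,
        area_px=n_fg,
        height_px=height_px,
        n_leaves=n_leaves,
        leaf_areas_px=leaf_areas,
        stem_area_px=stem_area,
    )


# ---------------------------------------------------------------------------
# Grain renderer
# ---------------------------------------------------------------------------

def _ellipse_patch(
    shape: tuple[int, int], r: float, c: float, a: float, b: float, theta: float
) -> tuple[tuple[int, int, int, int], np.ndarray]:
    """Boolean ellipse raster restricted to its bounding box (plus margin)."""
    h, w = shape
    pad = int(math.ceil(max(a, b))) + 4
    r0, r1 = max(0, int(r - pad)), min(h, int(r + pad + 1))
    c0, c1 = max(0, int(c - pad)), min(w, int(c + pad + 1))
    if r0 >= r1 or c0 >= c1:
        return (r0, r0, c0, c0), np.zeros((0, 0), dtype=bool)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - r
    dx = xx - c
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    return (r0, r1, c0, c1), (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _dilate(mask: np.ndarray, n: int = 1) -> np.ndarray:
    from scipy import ndimage as ndi

    return ndi.binary_dilation(mask, structure=np.ones((3, 3), bool), iterations=n)


def render_grains(
    n: int = 20,
    axis_ranges: tuple[tuple[float, float], tuple[float, float]] = ((22.0, 32.0), (9.0, 14.0)),
    touching_fraction: float = 0.0,
    canvas: tuple[int, int] = (600, 600),
    seed: int = 0,
    max_rejections: int = 5000,
    keep_masks: bool = False,
) -> GrainSceneTruth:
    """Scatter ``n`` bright ellipses on a dark background.

    A ``touching_fraction`` of the grains are laid out as edge-adjacent
    pairs (masks disjoint but 8-connected, so thresholding merges them);
    all other placements are mutually separated.
    """
    if n < 0 or not 0.0 <= touching_fraction < 1.0:
        raise ValueError("invalid n or touching_fraction")
    rng = np.random.default_rng(seed)
    h, w = canvas
    occupied = np.zeros((h, w), dtype=bool)
    sep = np.zeros((h, w), dtype=bool)  # occupied, dilated: keeps singles apart

    semi_axes: list[tuple[float, float]] = []
    orientations: list[float] = []
    centroids: list[tuple[float, float]] = []
    masks: list[np.ndarray] = []
    n_pairs = int(round(n * touching_fraction / 2.0))
    placements = ["pair"] * n_pairs + ["single"] * (n - 2 * n_pairs)

    def draw_axes() -> tuple[float, float]:
        a = rng.uniform(*axis_ranges[0])
        b = rng.uniform(*axis_ranges[1])
        return max(a, b), min(a, b)

    Box = tuple[int, int, int, int]

    def place_single() -> tuple[Box, np.ndarray, float, float, float, float, float] | None:
        for _ in range(max_rejections):
            a, b = draw_axes()
            theta = rng.uniform(0, math.pi)
            r = rng.uniform(a + 2, h - a - 2)
            c = rng.uniform(a + 2, w - a - 2)
            box, m = _ellipse_patch((h, w), r, c, a, b, theta)
            r0, r1, c0, c1 = box
            if not (_dilate(m) & sep[r0:r1, c0:c1]).any():
                return box, m, r, c, a, b, theta
        return None

    def accept(box: Box, m: np.ndarray, r: float, c: float, a: float, b: float, theta: float) -> None:
        r0, r1, c0, c1 = box
        occupied[r0:r1, c0:c1] |= m
        sep[r0:r1, c0:c1] |= _dilate(m, 2)
        semi_axes.append((a, b))
        orientations.append(theta)
        centroids.append((r, c))
        if keep_masks:
            full = np.zeros((h, w), dtype=bool)
            full[r0:r1, c0:c1] = m
            masks.append(full)

    touching_pairs = 0
    for kind in placements:
        first = place_single()
        if first is None:
            raise RuntimeError("canvas too small for requested grain count")
        box1, m1, r, c, a, b, theta = first
        accept(box1, m1, r, c, a, b, theta)
        full1 = np.zeros((h, w), dtype=bool)
        full1[box1[0] : box1[1], box1[2] : box1[3]] = m1
        if kind != "pair":
            continue
        # slide a second ellipse toward the first until just adjacent
        a2, b2 = draw_axes()
        theta2 = rng.uniform(0, math.pi)
        direction = rng.uniform(0, 2 * math.pi)
        placed = False
        for dist in np.arange(a + a2 + 3.0, 0.0, -0.5):
            r2 = r + dist * math.sin(direction)
            c2 = c + dist * math.cos(direction)
            if not (a2 + 2 <= r2 < h - a2 - 2 and a2 + 2 <= c2 < w - a2 - 2):
                break
            box2, m2 = _ellipse_patch((h, w), r2, c2, a2, b2, theta2)
            r0, r1, c0, c1 = box2
            if (m2 & occupied[r0:r1, c0:c1]).any():
                break
            near = _dilate(m2)
            if (near & full1[r0:r1, c0:c1]).any():  # adjacent to partner only
                if (near & occupied[r0:r1, c0:c1] & ~full1[r0:r1, c0:c1]).any():
                    break
                accept(box2, m2, r2, c2, a2, b2, theta2)
                touching_pairs += 1
                placed = True
                break
        if not placed:
            # fall back to a separated single so the count stays exact
            extra = place_single()
            if extra is None:
                raise RuntimeError("canvas too small for requested grain count")
            accept(*extra)

    image = np.zeros((h, w), dtype=np.uint8)
    image[:] = 12
    noise = rng.integers(0, 8, size=(h, w))
    image = (image + noise).astype(np.uint8)
    image[occupied] = rng.integers(200, 250, size=int(occupied.sum())).astype(np.uint8)
    return GrainSceneTruth(
        image=image,
        count=len(centroids),
        semi_axes=semi_axes,
        orientations=orientations,
        centroids=centroids,
        touching_pairs=touching_pairs,
        masks=masks if keep_masks else None,
    )


# ---------------------------------------------------------------------------
# Genotype / phenotype simulation
# ---------------------------------------------------------------------------

def simulate_genotypes(
    n: int,
    m: int,
    ld_rho: float = 0.0,
    n_subpops: int = 1,
    fst: float = 0.0,
    n_chrom: int = 1,
    pos_step: int = 500,
    seed: int = 0,
    het_rate: float = 0.0,
) -> SimPopulation:
    """Inbred genotypes with block LD and Balding-Nichols structure.

    Ancestral allele frequencies follow a clipped random walk along the
    genome (so adjacent SNPs share frequencies and the copying chain's
    adjacent correlation approaches ``ld_rho``); subpopulation frequencies
    are Balding-Nichols draws around the ancestral values at the given
    ``fst``.  Haplotypes come from a first-order copying chain; genotypes
    are ``2 x haplotype`` (optionally perturbed to heterozygous calls at
    ``het_rate``).
    """
    from .gwas import GenotypeMatrix

    if n < 2 or m < 2:
        raise ValueError("need n, m >= 2")
    if not (0.0 <= ld_rho < 1.0 and 0.0 <= fst < 1.0):
        raise ValueError("ld_rho and fst must be in [0, 1)")
    rng = np.random.default_rng(seed)

    # ancestral frequency random walk, clipped away from fixation
    p_anc = np.empty(m)
    p_anc[0] = rng.uniform(0.2, 0.8)
    steps = rng.normal(0.0, 0.015, size=m - 1)
    for j in range(1, m):
        p_anc[j] = min(0.9, max(0.1, p_anc[j - 1] + steps[j - 1]))

    subpop = np.repeat(np.arange(n_subpops), math.ceil(n / n_subpops))[:n]
    if fst > 0 and n_subpops > 1:
        shape = (1.0 - fst) / fst
        p_sub = np.empty((n_subpops, m))
        for k in range(n_subpops):
            p_sub[k] = rng.beta(p_anc * shape, (1.0 - p_anc) * shape)
            p_sub[k] = np.clip(p_sub[k], 0.02, 0.98)
    else:
        p_sub = np.tile(p_anc, (n_subpops, 1))

    hap = np.empty((n, m), dtype=np.int8)
    freq = p_sub[subpop]  # n x m
    u = rng.random((n, m))
    copy = rng.random((n, m)) < ld_rho
    hap[:, 0] = (u[:, 0] < freq[:, 0]).astype(np.int8)
    for j in range(1, m):
        fresh = (u[:, j] < freq[:, j]).astype(np.int8)
        hap[:, j] = np.where(copy[:, j], hap[:, j - 1], fresh)

    dosages = (2 * hap).astype(np.float64)
    if het_rate > 0:
        flip = rng.random((n, m)) < het_rate
        dosages[flip] = 1.0

    per_chrom = math.ceil(m / n_chrom)
    chrom = np.array([f"chr{j // per_chrom + 1}" for j in range(m)])
    pos = np.empty(m, dtype=np.int64)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = pos_step * (1 + np.arange(len(idx)))

    G = GenotypeMatrix(
        dosages=dosages,
        chrom=chrom,
        pos=pos,
        accessions=[f"acc{i:04d}" for i in range(n)],
    )
    return SimPopulation(
        genotypes=dosages,
        matrix=G,
        subpop=subpop,
        causal_idx=np.array([], dtype=int),
        causal_beta=np.array([]),
        h2_causal=0.0,
        h2_polygenic=0.0,
        seed=seed,
    )


def simulate_phenotype(
    pop: SimPopulation,
    causal_idx: Sequence[int] = (),
    h2_causal: float = 0.0,
    h2_polygenic: float = 0.0,
    h2_structure: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, dict]:
    """Phenotype with exact realized variance fractions.

    ``y`` is the sum of a causal term over ``causal_idx``, a polygenic term
    built from tiny effects at every SNP, an optional subpopulation-mean
    confounder (``h2_structure``), and Gaussian noise; each component is
    rescaled so its realized sample-variance fraction equals the nominal
    value.  Returns ``(y, info)`` where ``info`` carries the post-scaling
    causal effect sizes.
    """
    if h2_causal + h2_polygenic + h2_structure >= 1.0:
        raise ValueError("variance fractions must sum below 1")
    G = pop.matrix
    D = np.asarray(G.dosages)
    n, m = D.shape
    causal_idx = np.asarray(causal_idx, dtype=int)
    if causal_idx.size and (causal_idx.min() < 0 or causal_idx.max() >= m):
        raise ValueError("causal index out of range")
    rng = np.random.default_rng(seed)

    def scaled(component: np.ndarray, target_var: float) -> tuple[np.ndarray, float]:
        sd = component.std()
        if sd == 0 or target_var == 0:
            return np.zeros(n), 0.0
        factor = math.sqrt(target_var) / sd
        return (component - component.mean()) * factor, factor

    causal = np.zeros(n)
    base_beta = np.array([])
    if causal_idx.size and h2_causal > 0:
        base_beta = rng.normal(1.0, 0.2, size=causal_idx.size)
        causal = D[:, causal_idx] @ base_beta
    causal, f_causal = scaled(causal, h2_causal)

    poly = np.zeros(n)
    if h2_polygenic > 0:
        tiny = rng.normal(0.0, 1.0, size=m) / math.sqrt(m)
        poly = D @ tiny
    poly, _ = scaled(poly, h2_polygenic)

    structure = np.zeros(n)
    if h2_structure > 0 and len(np.unique(pop.subpop)) > 1:
        shifts = rng.normal(0.0, 1.0, size=int(pop.subpop.max()) + 1)
        structure = shifts[pop.subpop]
    structure, _ = scaled(structure, h2_structure)

    noise = rng.normal(0.0, 1.0, size=n)
    noise, _ = scaled(noise, 1.0 - h2_causal - h2_polygenic - h2_structure)

    y = causal + poly + structure + noise
    info = {
        "causal_idx": causal_idx,
        "causal_beta": base_beta * f_causal if base_beta.size else base_beta,
        "var_causal": float(causal.var()),
        "var_polygenic": float(poly.var()),
        "var_noise": float(noise.var()),
    }
    return y, info


def simulate_feature_trait_table(
    n: int,
    generating_family: str = "A",
    coefficients: Sequence[float] | None = None,
    noise_sd: float = 1.0,
    n_morph: int = 8,
    n_texture: int = 4,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Feature table plus a trait generated from a known model family.

    Columns: ``projected_area_px``, ``morph_1..n_morph``,
    ``texture_1..n_texture`` and ``trait``.  The generating family uses
    ``morph_1`` / ``texture_1`` as its true extra predictors.  Features are
    correlated with area at moderate strength, like real silhouettes.
    """
    if n < 20:
        raise ValueError("need n >= 20")
    if generating_family not in ("A", "AM", "AT", "ATM"):
        raise ValueError(f"invalid family {generating_family!r}")
    rng = np.random.default_rng(seed)
    area = rng.lognormal(mean=8.0, sigma=0.35, size=n)
    area_z = (area - area.mean()) / area.std()

    morph = {}
    for j in range(1, n_morph + 1):
        rho = 0.4 if j > 1 else 0.25
        morph[f"morph_{j}"] = rho * area_z + math.sqrt(1 - rho**2) * rng.normal(size=n)
    texture = {}
    for j in range(1, n_texture + 1):
        rho = 0.3
        texture[f"texture_{j}"] = rho * area_z + math.sqrt(1 - rho**2) * rng.normal(size=n)

    if coefficients is None:
        coefficients = {
            "A": (0.02,),
            "AM": (0.02, 25.0),
            "AT": (0.02, 25.0),
            "ATM": (0.02, 20.0, 20.0),
        }[generating_family]
    trait = 50.0 + coefficients[0] * area
    if generating_family in ("AM", "ATM"):
        trait = trait + coefficients[1] * morph["morph_1"]
    if generating_family == "AT":
        trait = trait + coefficients[1] * texture["texture_1"]
    if generating_family == "ATM":
        trait = trait + coefficients[2] * texture["texture_1"]
    trait = trait + rng.normal(0.0, noise_sd, size=n)

    table = pd.DataFrame({"projected_area_px": area, **morph, **texture, "trait": trait})
    table.insert(0, "plant_id", [f"plant{i:04d}" for i in range(n)])
    truth = {
        "family": generating_family,
        "coefficients": tuple(coefficients),
        "morph_pool": [f"morph_{j}" for j in range(1, n_morph + 1)],
        "texture_pool": [f"texture_{j}" for j in range(1, n_texture + 1)],
    }
    return table, truth
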