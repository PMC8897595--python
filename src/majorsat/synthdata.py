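"""Synthetic-data generators with exact ground truth.

Every input consumed by the analysis modules can be generated here, with a
truth table emitted alongside (never embedded in) the artifact:

- :func:`gen_tandem_repeat` — major-satellite-like tandem arrays (default
  234 bp units) with seed-match motifs planted at known positions.
- :func:`gen_repeatmasker_file` — RepeatMasker annotations in either the
  ``.out`` or the UCSC ``rmsk`` table dialect.
- :func:`gen_count_table` — RIP vs input small-RNA count tables with a known
  enriched/depleted miRNA subset.
- :func:`gen_ct_table` — qPCR Ct tables with known fold changes (assuming
  amplification efficiency 2, i.e. perfect doubling).
- :func:`gen_nuclear_images` — two-channel nuclear image stacks (DAPI with
  chromocenters, a marker channel with foci) with a controllable
  colocalization fraction.

All generators are deterministic given their spec and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlantedSite",
    "TandemRepeatSpec",
    "CountTableSpec",
    "ImageSceneSpec",
    "SceneTruth",
    "gen_tandem_repeat",
    "gen_repeatmasker_file",
    "gen_count_table",
    "gen_ct_table",
    "gen_nuclear_images",
    "write_scene",
    "simulate_coloc_counts",
]

_DNA = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# Tandem repeats with planted seed sites
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlantedSite:
    """A motif planted at a fixed offset in every k-th repeat unit."""

    motif: str
    offset_in_unit: int
    every_k_units: int = 1


@dataclass(frozen=True)
class TandemRepeatSpec:
    """Specification of a synthetic tandem-repeat array.

    Mouse major satellites are ~234 bp AT-rich units repeated in arrays of
    tens of kilobases; the defaults emulate that scale.  Planted motifs are
    confined to single units (no junction spanning), so expected site counts
    are exact by construction.
    """

    unit_length: int = 234
    n_units: int = 100
    gc_fraction: float = 0.35  # major satellites are AT-rich
    planted_sites: tuple[PlantedSite, ...] = ()
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("gc_fraction must be in [0, 1]")
        for site in self.planted_sites:
            bad = set(site.motif) - set("ACGT")
            if bad:
                raise ValueError(f"motif {site.motif!r} has non-ACGT characters")
            if site.every_k_units < 1:
                raise ValueError("every_k_units must be >= 1")
            if site.offset_in_unit < 0 or (
                site.offset_in_unit + len(site.motif) > self.unit_length
            ):
                raise ValueError(
                    f"motif {site.motif!r} at offset {site.offset_in_unit} does "
                    f"not fit within a {self.unit_length} bp unit"
                )


def _find_all(sequence: str, pattern: str) -> list[int]:
    hits, start = [], sequence.find(pattern)
    while start != -1:
        hits.append(start)
        start = sequence.find(pattern, start + 1)
    return hits


def gen_tandem_repeat(
    spec: TandemRepeatSpec, max_attempts: int = 1000
) -> tuple[str, pd.DataFrame]:
    """Generate a tandem-repeat sequence with motifs planted at known sites.

    Background bases are drawn i.i.d. at ``gc_fraction``; any spurious
    occurrence of a planted motif outside its truth positions is removed by
    redrawing the background bases under it (bounded rejection; a
    ``RuntimeError`` is raised after ``max_attempts`` sweeps or when a
    spurious occurrence consists solely of planted bases and can never be
    removed).

    Returns ``(sequence, truth)`` where ``truth`` has one row per planted
    site: columns ``motif, unit_index, start, end`` (0-based, half-open,
    array coordinates).
    """
    n = spec.unit_length * spec.n_units
    if n == 0:
        return "", pd.DataFrame(columns=["motif", "unit_index", "start", "end"])
    rng = np.random.default_rng(spec.rng_seed)
    p = np.array(
        [
            (1 - spec.gc_fraction) / 2,  # A
            spec.gc_fraction / 2,  # C
            spec.gc_fraction / 2,  # G
            (1 - spec.gc_fraction) / 2,  # T
        ]
    )
    seq = rng.choice(_DNA, size=n, p=p)

    planted = np.zeros(n, dtype=bool)
    truth_rows = []
    for site in spec.planted_sites:
        for unit in range(0, spec.n_units, site.every_k_units):
            start = unit * spec.unit_length + site.offset_in_unit
            end = start + len(site.motif)
            seq[start:end] = list(site.motif)
            planted[start:end] = True
            truth_rows.append(
                {"motif": site.motif, "unit_index": unit, "start": start, "end": end}
            )
    truth = pd.DataFrame(truth_rows, columns=["motif", "unit_index", "start", "end"])

    motifs = {s.motif for s in spec.planted_sites}
    truth_starts = {
        m: set(truth.loc[truth["motif"] == m, "start"]) for m in motifs
    }
    for _ in range(max_attempts):
        sequence = "".join(seq)
        spurious: list[tuple[int, int]] = []
        for m in motifs:
            for hit in _find_all(sequence, m):
                if hit not in truth_starts[m]:
                    spurious.append((hit, hit + len(m)))
        if not spurious:
            return sequence, truth
        for start, end in spurious:
            free = np.arange(start, end)[~planted[start:end]]
            if free.size == 0:
                raise RuntimeError(
                    "spurious motif occurrence overlaps only planted bases; "
                    "motif too permissive to reject"
                )
            seq[free] = rng.choice(_DNA, size=free.size, p=p)
    raise RuntimeError(
        f"could not remove spurious motif occurrences in {max_attempts} sweeps"
    )


# ---------------------------------------------------------------------------
# RepeatMasker annotation files
# ---------------------------------------------------------------------------

_OUT_HEADER = (
    "   SW   perc perc perc  query      position in query           matching"
    "       repeat              position in repeat\n"
    "score   div. del. ins.  sequence   begin  end          (left)  repeat"
    "         class/family      begin  end    (left)  ID\n"
    "\n"
)


def gen_repeatmasker_file(
    regions: Sequence[tuple[str, int, int, str, str]],
    dialect: str,
    path: str | Path,
) -> Path:
    """Write annotations (internal 0-based half-open intervals) to a file.

    ``regions`` are ``(chrom, start, end, repeat_name, strand)`` tuples.  The
    ``out`` dialect writes 1-based inclusive coordinates with ``C`` for the
    minus strand; ``ucsc_table`` writes 0-based half-open rmsk rows.  Both
    round-trip losslessly through :func:`majorsat.repeats.parse_annotations`.
    """
    if dialect not in ("out", "ucsc_table"):
        raise ValueError(f"unknown dialect {dialect!r}")
    for chrom, start, end, name, strand in regions:
        if not start < end:
            raise ValueError(f"require start < end, got {chrom}:{start}-{end}")
        if strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    path = Path(path)
    lines: list[str] = []
    if dialect == "out":
        lines.append(_OUT_HEADER)
        for i, (chrom, start, end, name, strand) in enumerate(regions, start=1):
            s = "C" if strand == "-" else "+"
            lines.append(
                f" 1000  0.0  0.0  0.0  {chrom} {start + 1} {end} (0) {s} "
                f"{name} Satellite 1 {end - start} (0) {i}\n"
            )
    else:
        for i, (chrom, start, end, name, strand) in enumerate(regions, start=1):
            fields = [
                "0", "1000", "0", "0", "0", chrom, str(start), str(end), "0",
                strand, name, "Satellite", "Satellite", "1", str(end - start),
                "0", str(i),
            ]
            lines.append("\t".join(fields) + "\n")
    path.write_text("".join(lines))
    return path


# ---------------------------------------------------------------------------
# RIP vs input small-RNA count tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountTableSpec:
    """Specification of a synthetic RIP/input small-RNA count table.

    Per-miRNA relative abundances follow a log-normal with ``spread_log2_sd``
    log2 units of standard deviation (a dynamic range of several orders of
    magnitude, as in deep small-RNA sequencing, which leaves roughly half of
    the miRNAs below a log2(cpm+1) = 5 expression floor at default sizes).
    Enriched/depleted miRNAs get their RIP abundance multiplied by
    ``2**(+/-effect_log2fc)``; planted-effect miRNAs are drawn from the
    above-median expression stratum, since loading calls are only meaningful
    for expressed miRNAs.
    """

    n_mirnas: int = 500
    enriched_ids: tuple[str, ...] = ()
    depleted_ids: tuple[str, ...] = ()
    base_expression: float = 25.0
    spread_log2_sd: float = 4.5
    effect_log2fc: float = 2.0
    library_size_input: int = 1_000_000
    library_size_rip: int = 1_000_000
    noise_model: str = "negative_binomial"
    dispersion: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if set(self.enriched_ids) & set(self.depleted_ids):
            raise ValueError("enriched and depleted id sets must be disjoint")
        if self.library_size_input <= 0 or self.library_size_rip <= 0:
            raise ValueError("library sizes must be positive")
        if self.noise_model not in ("multinomial", "negative_binomial"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    def mirna_ids(self) -> list[str]:
        return [f"miR-{i:04d}" for i in range(self.n_mirnas)]

    @staticmethod
    def with_random_effects(
        n_mirnas: int,
        n_enriched: int,
        n_depleted: int = 0,
        rng_seed: int = 0,
        **kwargs,
    ) -> "CountTableSpec":
        """Pick disjoint enriched/depleted id sets at random."""
        rng = np.random.default_rng(rng_seed)
        ids = [f"miR-{i:04d}" for i in range(n_mirnas)]
        chosen = rng.choice(n_mirnas, size=n_enriched + n_depleted, replace=False)
        return CountTableSpec(
            n_mirnas=n_mirnas,
            enriched_ids=tuple(ids[i] for i in chosen[:n_enriched]),
            depleted_ids=tuple(ids[i] for i in chosen[n_enriched:]),
            rng_seed=rng_seed,
            **kwargs,
        )


def gen_count_table(spec: CountTableSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a raw count table (columns ``input``, ``rip``) plus truth.

    Expected per-miRNA cpm differs between RIP and input by exactly
    ``+effect_log2fc`` log2 units for enriched ids, ``-effect_log2fc`` for
    depleted ids and 0 otherwise, before sampling noise.  With
    ``negative_binomial`` noise and ``dispersion == 0`` the table contains
    the (possibly non-integer) expected counts themselves, so null examples
    hold exactly.

    Truth columns: ``mirna_id, true_class, expected_cpm_input,
    expected_cpm_rip`` (``true_class`` in {enriched, depleted, neutral}).
    """
    ids = spec.mirna_ids()
    unknown = (set(spec.enriched_ids) | set(spec.depleted_ids)) - set(ids)
    if unknown:
        raise ValueError(f"effect ids not in table: {sorted(unknown)}")
    rng = np.random.default_rng(spec.rng_seed)
    z = rng.normal(0.0, spec.spread_log2_sd, size=spec.n_mirnas)
    effect_idx = [i for i, m in enumerate(ids)
                  if m in set(spec.enriched_ids) | set(spec.depleted_ids)]
    # effect miRNAs come from the expressed (above-median) stratum
    z[effect_idx] = np.abs(z[effect_idx])
    abundance = spec.base_expression * np.power(2.0, z)

    fc = np.zeros(spec.n_mirnas)
    enriched = np.isin(ids, list(spec.enriched_ids))
    depleted = np.isin(ids, list(spec.depleted_ids))
    fc[enriched] = spec.effect_log2fc
    fc[depleted] = -spec.effect_log2fc

    cpm_input = abundance / abundance.sum() * 1e6
    cpm_rip = cpm_input * np.power(2.0, fc)
    mu_input = cpm_input * spec.library_size_input / 1e6
    mu_rip = cpm_rip * spec.library_size_rip / 1e6

    def sample(mu: np.ndarray, libsize: int) -> np.ndarray:
        if spec.noise_model == "multinomial":
            return rng.multinomial(libsize, mu / mu.sum()).astype(float)
        if spec.dispersion == 0:
            return mu.copy()
        size = 1.0 / spec.dispersion
        return rng.negative_binomial(size, size / (size + mu)).astype(float)

    table = pd.DataFrame(
        {"input": sample(mu_input, spec.library_size_input),
         "rip": sample(mu_rip, spec.library_size_rip)},
        index=pd.Index(ids, name="mirna_id"),
    )
    true_class = np.where(enriched, "enriched", np.where(depleted, "depleted", "neutral"))
    truth = pd.DataFrame(
        {
            "mirna_id": ids,
            "true_class": true_class,
            "expected_cpm_input": cpm_input,
            "expected_cpm_rip": cpm_rip,
        }
    )
    return table, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def gen_ct_table(
    targets: Sequence[tuple[str, float, float]],
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    n_replicates: int = 3,
    reference_gene: str = "reference",
    control_condition: str = "control",
    sample_condition: str = "treated",
) -> pd.DataFrame:
    """Generate a Ct table with known fold changes.

    ``targets`` are ``(name, true_fold, ct_reference)`` tuples: in the
    control condition both the target and the reference gene amplify at
    ``ct_reference`` cycles; in the sample condition the target's Ct is
    lowered by log2(true_fold) (perfect doubling per cycle), so the 2^-ddCt
    estimator recovers ``true_fold`` exactly at zero noise.  Gaussian noise
    of ``noise_sd`` cycles is added independently to every replicate row.

    Returns a DataFrame with columns ``sample, target, assay, ct, replicate``
    (assay is ``RT`` throughout); write with ``df.to_csv`` for the CSV form.
    """
    rng = np.random.default_rng(rng_seed)
    rows = []
    for name, true_fold, ct_reference in targets:
        if true_fold <= 0:
            raise ValueError(f"true_fold must be positive, got {true_fold}")
        base = {
            (control_condition, reference_gene): ct_reference,
            (sample_condition, reference_gene): ct_reference,
            (control_condition, name): ct_reference,
            (sample_condition, name): ct_reference - math.log2(true_fold),
        }
        for (sample, target), ct in base.items():
            if target == reference_gene and rows and any(
                r["sample"] == sample and r["target"] == reference_gene for r in rows
            ):
                continue  # one reference-gene series per condition
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "sample": sample,
                        "target": target,
                        "assay": "RT",
                        "ct": ct + (rng.normal(0.0, noise_sd) if noise_sd else 0.0),
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows, columns=["sample", "target", "assay", "ct", "replicate"])


# ---------------------------------------------------------------------------
# Two-channel nuclear image scenes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImageSceneSpec:
    """Specification of a synthetic two-channel nuclear scene.

    The DAPI channel holds smooth nuclear disks with brighter Gaussian blobs
    at chromocenter positions; the marker channel holds Gaussian spots at
    focus positions.  Each marker focus is colocalized (centred on a
    chromocenter) with probability ``p_coloc``, otherwise placed in the
    nucleoplasm at least ``2 * chromocenter_radius_px`` from every
    chromocenter centre.  Foci live in a single focal plane; other z slices
    carry attenuated copies, so a max projection is required and sufficient.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_nuclei: int = 5
    nucleus_radius_px: tuple[float, float] = (40.0, 55.0)
    chromocenters_per_nucleus: float = 5.0
    chromocenter_radius_px: float = 6.0
    marker_foci_per_nucleus: float = 8.0
    p_coloc: float = 0.5
    snr: float = 10.0
    z_slices: int = 3
    bit_depth: int = 16
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_coloc <= 1.0):
            raise ValueError("p_coloc must be in [0, 1]")
        if self.z_slices < 1:
            raise ValueError("z_slices must be >= 1")
        if self.nucleus_radius_px[0] > self.nucleus_radius_px[1]:
            raise ValueError("nucleus_radius_px must be (min, max)")
        if self.bit_depth != 16:
            raise ValueError("only 16-bit output is supported")


@dataclass
class SceneTruth:
    """Ground truth for one scene: nucleus table and object table.

    ``nuclei``: columns ``nucleus_id, row, col, radius``.
    ``objects``: columns ``kind`` ({chromocenter, marker_focus}),
    ``nucleus_id, row, col, colocalized`` (boolean for marker foci, NA for
    chromocenters).
    """

    nuclei: pd.DataFrame
    objects: pd.DataFrame


# render amplitudes (fractions of the 16-bit range); noise sd = amplitude/snr
_DAPI_DISK = 0.25
_DAPI_BLOB = 0.55
_MARKER_DISK = 0.10
_MARKER_SPOT = 0.60
_BLOB_SIGMA_FACTOR = 0.55  # blob sigma = factor * chromocenter radius
_SPOT_SIGMA = 2.5
_Z_ATTENUATION = 0.4


def _place_nuclei(spec: ImageSceneSpec, rng: np.random.Generator) -> pd.DataFrame:
    h, w = spec.image_shape
    rmin, rmax = spec.nucleus_radius_px
    placed: list[tuple[float, float, float]] = []
    for _ in range(spec.n_nuclei):
        for _attempt in range(1000):
            r = rng.uniform(rmin, rmax)
            row = rng.uniform(r + 3, h - r - 3)
            col = rng.uniform(r + 3, w - r - 3)
            if all(
                math.hypot(row - pr, col - pc) > r + prr + 4
                for pr, pc, prr in placed
            ):
                placed.append((row, col, r))
                break
        else:
            raise RuntimeError(
                f"could not place {spec.n_nuclei} non-overlapping nuclei in "
                f"{spec.image_shape} after bounded attempts"
            )
    return pd.DataFrame(
        [
            {"nucleus_id": i + 1, "row": r0, "col": c0, "radius": rr}
            for i, (r0, c0, rr) in enumerate(placed)
        ]
    )


def _place_objects(
    spec: ImageSceneSpec, nuclei: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    c_rad = spec.chromocenter_radius_px
    for nuc in nuclei.itertuples():
        # chromocenters: mutually separated so detection can resolve them
        n_chromo = int(rng.poisson(spec.chromocenters_per_nucleus))
        centers: list[tuple[float, float]] = []
        for _ in range(n_chromo):
            for _attempt in range(200):
                rad = rng.uniform(0, 0.70 * nuc.radius)
                theta = rng.uniform(0, 2 * math.pi)
                cr = nuc.row + rad * math.sin(theta)
                cc = nuc.col + rad * math.cos(theta)
                if all(
                    math.hypot(cr - a, cc - b) >= 4.0 * c_rad for a, b in centers
                ):
                    centers.append((cr, cc))
                    break
            # a chromocenter that cannot be placed is silently dropped:
            # truth reflects what the image actually contains
        for cr, cc in centers:
            rows.append(
                {
                    "kind": "chromocenter",
                    "nucleus_id": nuc.nucleus_id,
                    "row": cr,
                    "col": cc,
                    "colocalized": pd.NA,
                }
            )
        # marker foci: each colocalized focus claims a distinct chromocenter
        # so two planted foci never collapse into one unresolvable spot; when
        # every chromocenter is claimed the focus falls back to a
        # non-colocalized placement with its truth flag set accordingly (the
        # realized colocalization fraction therefore drops slightly below
        # p_coloc when foci outnumber chromocenters)
        n_foci = int(rng.poisson(spec.marker_foci_per_nucleus))
        unused = list(range(len(centers)))
        focus_positions: list[tuple[float, float]] = []
        for _ in range(n_foci):
            wants_coloc = rng.random() < spec.p_coloc
            if wants_coloc and unused:
                k = unused.pop(int(rng.integers(len(unused))))
                rows.append(
                    {
                        "kind": "marker_focus",
                        "nucleus_id": nuc.nucleus_id,
                        "row": centers[k][0],
                        "col": centers[k][1],
                        "colocalized": True,
                    }
                )
                focus_positions.append(centers[k])
                continue
            for _attempt in range(500):
                rad = rng.uniform(0, 0.80 * nuc.radius)
                theta = rng.uniform(0, 2 * math.pi)
                fr = nuc.row + rad * math.sin(theta)
                fc = nuc.col + rad * math.cos(theta)
                far_from_chromo = all(
                    math.hypot(fr - a, fc - b) >= 2.0 * c_rad + 1.0
                    for a, b in centers
                )
                separated = all(
                    math.hypot(fr - a, fc - b) >= 10.0 for a, b in focus_positions
                )
                if far_from_chromo and separated:
                    rows.append(
                        {
                            "kind": "marker_focus",
                            "nucleus_id": nuc.nucleus_id,
                            "row": fr,
                            "col": fc,
                            "colocalized": False,
                        }
                    )
                    focus_positions.append((fr, fc))
                    break
            # an unplaceable focus is dropped; truth stays exact
    return pd.DataFrame(
        rows, columns=["kind", "nucleus_id", "row", "col", "colocalized"]
    )


def _add_gaussian(img: np.ndarray, row: float, col: float, sigma: float,
                  amplitude: float) -> None:
    h, w = img.shape
    half = int(math.ceil(4 * sigma))
    r0, r1 = max(0, int(row) - half), min(h, int(row) + half + 1)
    c0, c1 = max(0, int(col) - half), min(w, int(col) + half + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    img[r0:r1, c0:c1] += amplitude * np.exp(
        -((rr - row) ** 2 + (cc - col) ** 2) / (2 * sigma**2)
    )


def _nuclear_disks(shape: tuple[int, int], nuclei: pd.DataFrame,
                   amplitude: float) -> np.ndarray:
    img = np.zeros(shape, dtype=float)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for nuc in nuclei.itertuples():
        d = np.hypot(rr - nuc.row, cc - nuc.col)
        img += amplitude / (1.0 + np.exp((d - nuc.radius) / 1.5))
    return img


def gen_nuclear_images(
    spec: ImageSceneSpec,
) -> tuple[np.ndarray, np.ndarray, SceneTruth]:
    """Render one two-channel scene; returns (dapi, marker, truth).

    Both image arrays have shape ``(z_slices, H, W)`` and dtype uint16.
    Chromocenter blobs and marker spots live in the middle z slice; other
    slices carry them attenuated (nuclear disks span all slices).  Additive
    Gaussian noise per slice has sd = structure amplitude / snr
    (``snr=math.inf`` gives noise-free images).
    """
    rng = np.random.default_rng(spec.rng_seed)
    nuclei = _place_nuclei(spec, rng)
    objects = _place_objects(spec, nuclei, rng)
    h, w = spec.image_shape
    blob_sigma = _BLOB_SIGMA_FACTOR * spec.chromocenter_radius_px

    dapi_disk = _nuclear_disks((h, w), nuclei, _DAPI_DISK)
    marker_disk = _nuclear_disks((h, w), nuclei, _MARKER_DISK)
    dapi_struct = np.zeros((h, w), dtype=float)
    marker_struct = np.zeros((h, w), dtype=float)
    for obj in objects.itertuples():
        if obj.kind == "chromocenter":
            _add_gaussian(dapi_struct, obj.row, obj.col, blob_sigma, _DAPI_BLOB)
        else:
            _add_gaussian(marker_struct, obj.row, obj.col, _SPOT_SIGMA, _MARKER_SPOT)

    focal = spec.z_slices // 2
    noise_dapi = 0.0 if math.isinf(spec.snr) else _DAPI_BLOB / spec.snr
    noise_marker = 0.0 if math.isinf(spec.snr) else _MARKER_SPOT / spec.snr

    def stack(disk: np.ndarray, struct: np.ndarray, noise_sd: float) -> np.ndarray:
        out = np.empty((spec.z_slices, h, w), dtype=np.uint16)
        for z in range(spec.z_slices):
            att = _Z_ATTENUATION ** abs(z - focal)
            plane = disk + att * struct
            if noise_sd:
                plane = plane + rng.normal(0.0, noise_sd, size=(h, w))
            out[z] = (np.clip(plane, 0.0, 1.0) * 65535).astype(np.uint16)
        return out

    dapi = stack(dapi_disk, dapi_struct, noise_dapi)
    marker = stack(marker_disk, marker_struct, noise_marker)
    return dapi, marker, SceneTruth(nuclei=nuclei, objects=objects)


def write_scene(spec: ImageSceneSpec, outdir: str | Path,
                prefix: str = "scene") -> dict[str, Path]:
    """Render a scene and write DAPI/marker TIFF stacks plus truth CSVs."""
    import tifffile

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dapi, marker, truth = gen_nuclear_images(spec)
    paths = {
        "dapi": outdir / f"{prefix}_dapi.tif",
        "marker": outdir / f"{prefix}_marker.tif",
        "nuclei": outdir / f"{prefix}_truth_nuclei.csv",
        "objects": outdir / f"{prefix}_truth_objects.csv",
    }
    tifffile.imwrite(paths["dapi"], dapi)
    tifffile.imwrite(paths["marker"], marker)
    truth.nuclei.to_csv(paths["nuclei"], index=False)
    truth.objects.to_csv(paths["objects"], index=False)
    return paths


def simulate_coloc_counts(
    n_nuclei: int,
    foci_per_nucleus_mean: float,
    p_coloc: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-nucleus colocalized focus counts under the scene generative model.

    Focus counts are Poisson(``foci_per_nucleus_mean``); each focus is
    colocalized independently with probability ``p_coloc``.  This samples the
    count distribution directly, without rendering images — useful for
    statistical calibration at scale.
    """
    totals = rng.poisson(foci_per_nucleus_mean, size=n_nuclei)
    return rng.binomial(totals, p_coloc)
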