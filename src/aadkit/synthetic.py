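"""Synthetic cohorts, spectra, burn events and stained-section images.

The generators emulate the structure of an acute type-A aortic dissection
study: three tissue regions — false lumen (FL), dissection flap (FP) and
true lumen (TL) — sampled from a small surgical cohort (10/10/6 samples by
default), with the FL population additionally composed of three latent
sub-groups.  Every generator returns its ground truth so downstream stages
(preprocessing, classification, clustering, image quantification) can be
tested without any external data.

Scientific caricature, not physics: spectra are Gaussian peaks on a binned
m/z axis with multiplicative log-normal noise; feature-table variables are
log-normal (guaranteeing positivity); stained sections are flat-colour
paintings with pixel-exact composition.  See docs/methods.md for what these
do and do not capture.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .reims import RawRun

TISSUE_TYPES = ("FL", "FP", "TL")

# Standardized log-scale location shifts of the FL group relative to FP/TL,
# in units of the variable's log-SD, at class_effect = 1.  Negative values
# encode the degraded false-lumen phenotype: softer (lower shear storage and
# loss moduli), GAG-depleted, partially elastolysed media.
_FL_SHIFT_SD = {
    "g_prime_kpa": -1.5,
    "g_double_prime_kpa": -1.5,
    "gag_ug_mg": -1.5,
    "elastin_ug_mg": -0.75,
    "collagen_ug_mg": 0.0,
    "age_years": 0.0,
    "indexed_aortic_size": 0.0,
}

# (median, log-SD) of each variable for the FP/TL reference population.
_VARIABLE_PARAMS = {
    "g_prime_kpa": (25.0, 0.35),
    "g_double_prime_kpa": (8.0, 0.35),
    "collagen_ug_mg": (90.0, 0.25),
    "elastin_ug_mg": (130.0, 0.30),
    "gag_ug_mg": (18.0, 0.35),
    "age_years": (57.0, 0.20),
    "indexed_aortic_size": (12.3, 0.20),
}


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters shared by the cohort generators.

    ``class_effect`` scales the FL-vs-rest separation (1.0 gives the default
    ~1.5-SD shift on the affected variables and full-strength spectral class
    markers); ``subcluster_effect`` scales the FL sub-template separation;
    ``noise_cv`` is the multiplicative coefficient of variation applied to
    every spectral bin.  Identical seeds give bit-identical outputs.
    """

    n_fl: int = 10
    n_fp: int = 10
    n_tl: int = 6
    class_effect: float = 1.0
    n_subclusters: int = 3
    subcluster_effect: float = 2.0
    noise_cv: float = 0.2
    seed: int = 0
    pieces_per_patient: int = 1

    def __post_init__(self) -> None:
        for name in ("n_fl", "n_fp", "n_tl"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_subclusters < 1:
            raise ValueError("n_subclusters must be >= 1")
        for name in ("class_effect", "subcluster_effect", "noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pieces_per_patient < 1:
            raise ValueError("pieces_per_patient must be >= 1")


@dataclass
class SyntheticGroundTruth:
    """Per-sample generation record (labels and, for images, painted fractions)."""

    sample_id: str
    tissue_type: str
    patient_id: str
    subcluster: int | None = None
    true_collagen_fraction: float | None = None
    true_elastin_fraction: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def _iter_samples(config: CohortConfig):
    """Yield (sample_id, tissue_type, patient_id, subcluster) in fixed order.

    FL samples are assigned to the ``n_subclusters`` latent sub-groups
    round-robin (10 FL with 3 sub-groups -> sizes 4/3/3).
    """
    counts = {"FL": config.n_fl, "FP": config.n_fp, "TL": config.n_tl}
    for tissue in TISSUE_TYPES:
        for i in range(counts[tissue]):
            patient = f"P{tissue}{i // config.pieces_per_patient + 1:02d}"
            sub = (i % config.n_subclusters) if tissue == "FL" else None
            yield f"{tissue}{i + 1:02d}", tissue, patient, sub


def generate_feature_table(
    config: CohortConfig,
) -> tuple[pd.DataFrame, list[SyntheticGroundTruth]]:
    """Per-sample biomechanical/biochemical/clinical variables, all positive.

    Variables are log-normal; the FL group is shifted down on G', G'' and
    GAG (and mildly on elastin) by ``class_effect`` x the per-variable
    default shift, emulating the mechanically compromised false-lumen wall.
    With ``class_effect=0`` the three groups are exchangeable.
    """
    rng = np.random.default_rng(config.seed)
    rows, truths = [], []
    for sample_id, tissue, patient, sub in _iter_samples(config):
        row = {"sample_id": sample_id, "tissue_type": tissue, "patient_id": patient}
        for var, (median, sigma) in _VARIABLE_PARAMS.items():
            shift = _FL_SHIFT_SD[var] * config.class_effect if tissue == "FL" else 0.0
            z = rng.standard_normal()
            row[var] = median * math.exp(sigma * (z + shift))
        rows.append(row)
        truths.append(SyntheticGroundTruth(sample_id, tissue, patient, sub))
    return pd.DataFrame(rows), truths


@dataclass
class SpectrumSet:
    """TIC-normalized binned spectra with labels and planted-marker bookkeeping.

    ``intensities`` is samples x bins (rows sum to 1); ``labels`` carries
    tissue type, patient and FL subcluster per sample; ``class_marker_bins``
    and ``subcluster_marker_bins`` record the bin indices at the centres of
    the peaks planted for each class / FL sub-template.
    """

    intensities: pd.DataFrame
    labels: pd.DataFrame
    mz_centers: np.ndarray
    class_marker_bins: dict = field(default_factory=dict)
    subcluster_marker_bins: dict = field(default_factory=dict)

    @property
    def X(self) -> np.ndarray:
        return self.intensities.to_numpy(float)

    @property
    def tissue_type(self) -> np.ndarray:
        return self.labels["tissue_type"].to_numpy()


def _balance_merge_costs(
    base_template: np.ndarray,
    sub_templates: list[np.ndarray],
    sizes: np.ndarray,
    n_iter: int = 40,
) -> np.ndarray:
    """Amplitude scale factors equalizing the pairwise Ward merge costs.

    The Ward cost of merging tight sub-groups i and j with centroid
    separation d_ij is (n_i n_j / (n_i + n_j)) d_ij^2.  Sub-templates are
    planted as a *symmetric* split: no pair may be systematically cheaper
    to merge than another, otherwise that pair's union — not only the
    planted sub-groups — would be reproduced by every bootstrap replicate.
    Because TIC normalization couples marker mass to the whole spectrum,
    the costs are balanced empirically: noise-free normalized centroids are
    recomputed while marker amplitude scales are adjusted by fixed-point
    iteration until the costs tie.
    """
    k = len(sub_templates)
    s = np.ones(k)
    if k < 2:
        return s
    # sub-groups that received no samples still get a template; weight them
    # as singletons so the cost system stays well defined
    sizes = np.maximum(np.asarray(sizes, dtype=float), 1.0)
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    c_ij = {
        (i, j): sizes[i] * sizes[j] / (sizes[i] + sizes[j]) for i, j in pairs
    }
    for _ in range(n_iter):
        cents = []
        for j in range(k):
            t = base_template + s[j] * sub_templates[j]
            cents.append(t / t.sum())
        costs = {
            (i, j): c_ij[(i, j)] * float(np.sum((cents[i] - cents[j]) ** 2))
            for i, j in pairs
        }
        mean_cost = np.mean(list(costs.values()))
        if max(costs.values()) <= 1.02 * min(costs.values()):
            break
        for j in range(k):
            incident = [costs[p] for p in pairs if j in p]
            s[j] *= (mean_cost / np.mean(incident)) ** 0.25
    return s


class _PeakSlots:
    """Non-colliding peak placement on a jittered grid of m/z slots.

    Slots are spaced ``spacing`` Da apart across [lo, hi]; each draw takes a
    random unused slot inside the requested band and jitters it by up to a
    quarter spacing, guaranteeing a minimum separation of spacing/2 between
    any two peaks without rejection sampling.
    """

    def __init__(self, rng, lo: float, hi: float, spacing: float):
        self.rng = rng
        self.spacing = spacing
        self.available = list(np.arange(lo + spacing / 2, hi, spacing))

    def draw(self, n: int, lo: float, hi: float) -> list[float]:
        idx = [i for i, s in enumerate(self.available) if lo <= s <= hi]
        if len(idx) < n:
            raise RuntimeError("not enough m/z slots in the requested band")
        chosen = self.rng.choice(idx, size=n, replace=False)
        out = []
        for i in sorted(chosen, reverse=True):
            slot = self.available.pop(i)
            out.append(float(slot + self.rng.uniform(-0.25, 0.25) * self.spacing))
        return out


def generate_spectrum_set(
    config: CohortConfig,
    n_bins: int = 1150,
    mz_lo: float = 50.0,
    mz_hi: float = 1200.0,
) -> tuple[SpectrumSet, list[SyntheticGroundTruth]]:
    """Binned negative-mode spectra for the whole cohort.

    Templates share a ~30-peak backbone concentrated in the lipid-rich
    600-900 m/z region; each tissue class adds 8 marker peaks scaled by
    ``class_effect``; each FL sub-template adds 6 marker peaks scaled by
    ``subcluster_effect`` (equal marker counts keep the sub-template
    centroids roughly equidistant).  Per-bin multiplicative log-normal noise
    has coefficient of variation ``noise_cv``; rows are TIC-normalized.
    """
    if mz_lo >= mz_hi:
        raise ValueError("mz_lo must be below mz_hi")
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    rng = np.random.default_rng(config.seed)
    edges = np.linspace(mz_lo, mz_hi, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    bin_width = edges[1] - edges[0]
    peak_sigma = max(2.0, bin_width)  # Da

    def template_of(positions, amplitudes):
        t = np.zeros(n_bins)
        for pos, amp in zip(positions, amplitudes):
            t += amp * np.exp(-((centers - pos) ** 2) / (2 * peak_sigma**2))
        return t

    # slot spacing: as wide as resolution allows while keeping enough slots
    # for backbone + class + sub-template peaks even at coarse binning
    spacing = min(3 * peak_sigma, (mz_hi - mz_lo) / 160)
    slots = _PeakSlots(rng, mz_lo, mz_hi, spacing=spacing)
    lipid_lo, lipid_hi = max(mz_lo, 600.0), min(mz_hi, 900.0)
    if lipid_lo >= lipid_hi:  # narrow custom ranges: fall back to full span
        lipid_lo, lipid_hi = mz_lo, mz_hi
    # class / sub-template markers get a wider lipid-ish band so they do not
    # exhaust the dense backbone region
    marker_lo = max(mz_lo, 550.0)
    marker_hi = min(mz_hi, 1050.0)
    if marker_lo >= marker_hi:
        marker_lo, marker_hi = mz_lo, mz_hi
    backbone_pos = slots.draw(22, lipid_lo, lipid_hi)
    backbone_pos += slots.draw(8, mz_lo + 0.05 * (mz_hi - mz_lo), lipid_lo)
    backbone_amp = rng.uniform(0.5, 2.0, size=len(backbone_pos))
    backbone = template_of(backbone_pos, backbone_amp) + 0.02

    class_templates, class_bins = {}, {}
    for tissue in TISSUE_TYPES:
        pos = slots.draw(8, marker_lo, marker_hi)
        amp = config.class_effect * rng.uniform(0.8, 2.0, size=8)
        class_templates[tissue] = backbone + template_of(pos, amp)
        class_bins[tissue] = [int(np.argmin(np.abs(centers - p))) for p in pos]

    # The FL sub-templates are planted as a symmetric split (see
    # _balance_merge_costs): marker amplitudes are rescaled so no pair of
    # sub-groups is systematically cheaper for Ward to merge than another.
    sub_sizes = np.bincount(
        [i % config.n_subclusters for i in range(config.n_fl)],
        minlength=config.n_subclusters,
    )
    sub_templates, sub_bins = {}, {}
    raw_subs = []
    for j in range(config.n_subclusters):
        pos = slots.draw(6, marker_lo, marker_hi)
        amp = config.subcluster_effect * rng.uniform(0.8, 2.0, size=6)
        raw_subs.append(template_of(pos, amp))
        sub_bins[j] = [int(np.argmin(np.abs(centers - p))) for p in pos]
    if config.subcluster_effect > 0:
        scale = _balance_merge_costs(class_templates["FL"], raw_subs, sub_sizes)
    else:
        scale = np.ones(config.n_subclusters)
    for j in range(config.n_subclusters):
        sub_templates[j] = scale[j] * raw_subs[j]

    sigma_log = math.sqrt(math.log1p(config.noise_cv**2))
    rows, labels, truths = [], [], []
    for sample_id, tissue, patient, sub in _iter_samples(config):
        template = class_templates[tissue].copy()
        if tissue == "FL":
            template = template + sub_templates[sub]
        noise = np.exp(sigma_log * rng.standard_normal(n_bins)) if sigma_log > 0 else 1.0
        spectrum = template * noise
        spectrum = spectrum / spectrum.sum()
        rows.append(spectrum)
        labels.append(
            {
                "sample_id": sample_id,
                "tissue_type": tissue,
                "patient_id": patient,
                "subcluster": sub,
            }
        )
        truths.append(SyntheticGroundTruth(sample_id, tissue, patient, sub))

    intensities = pd.DataFrame(
        np.vstack(rows),
        index=[t["sample_id"] for t in labels],
        columns=np.round(centers, 4),
    )
    sset = SpectrumSet(
        intensities=intensities,
        labels=pd.DataFrame(labels).set_index("sample_id", drop=False),
        mz_centers=centers,
        class_marker_bins=class_bins,
        subcluster_marker_bins=sub_bins,
    )
    return sset, truths


def generate_burn_event(
    duration_s: float,
    scan_rate_hz: float = 1.0,
    seed: int = 0,
    baseline_tic: float = 1000.0,
    baseline_noise_cv: float = 0.05,
    burn_factor: float = 10.0,
    n_flank_scans: int | None = None,
    peaks_per_scan: int = 80,
) -> RawRun:
    """A raw run containing one irregular burn event flanked by baseline scans.

    TIC rises to roughly ``burn_factor`` x baseline for ``duration_s x
    scan_rate_hz`` scans with a jagged ("uneven") envelope; at least 5
    baseline scans flank the event on each side (by default the flanks are
    at least as long as the event, as in real acquisitions where burns are
    a minority of the run, so a median-TIC baseline is well defined).  With
    zero baseline noise the off-event TIC equals ``baseline_tic`` exactly.
    Durations outside the instrument's typical 10-30 s window are generated
    with a warning.
    """
    if not 10.0 <= duration_s <= 30.0:
        warnings.warn(
            f"burn duration {duration_s} s is outside the typical 10-30 s range",
            stacklevel=2,
        )
    if scan_rate_hz <= 0:
        raise ValueError("scan_rate_hz must be positive")
    rng = np.random.default_rng(seed)
    n_event = max(1, round(duration_s * scan_rate_hz))
    if n_flank_scans is None:
        n_flank_scans = max(10, n_event)
    if n_flank_scans < 5:
        raise ValueError("need at least 5 flanking baseline scans on each side")
    n_total = n_event + 2 * n_flank_scans

    target_tic = np.empty(n_total)
    for i in range(n_total):
        if n_flank_scans <= i < n_flank_scans + n_event:
            # jagged elevated envelope: uneven by construction
            target_tic[i] = baseline_tic * burn_factor * rng.uniform(0.6, 1.4)
        else:
            noise = (
                math.exp(baseline_noise_cv * rng.standard_normal())
                if baseline_noise_cv > 0
                else 1.0
            )
            target_tic[i] = baseline_tic * noise

    scans = []
    for i in range(n_total):
        mz = np.sort(rng.uniform(50.0, 1200.0, size=peaks_per_scan))
        raw = rng.uniform(0.1, 1.0, size=peaks_per_scan)
        inten = raw * (target_tic[i] / raw.sum())  # exact per-scan TIC
        scans.append((mz, inten))
    times = np.arange(n_total) / scan_rate_hz
    return RawRun(scans, times)


# ---------------------------------------------------------------------------
# stained-section images

# Flat-colour palettes chosen so each pixel class lands on the correct side
# of every downstream decision rule: collagen hues have collagen index > 1
# (the nominal threshold) but darkness < 0.5; elastin hues are grey-to-black
# (darkness > 0.5, collagen index < 1); the counterstain and the blank-slide
# background fail both stain rules.  Background blue (251) is the modal blue
# value, so the tissue mask is exact.
VVG_BACKGROUND = (248, 248, 251)
VVG_COLLAGEN_PALETTE = ((230, 150, 180), (210, 80, 160), (200, 85, 115))
VVG_ELASTIN_PALETTE = ((30, 30, 30), (70, 70, 70), (105, 105, 105))
VVG_COUNTERSTAIN = (225, 200, 150)
PSR_BACKGROUND = (248, 248, 251)
PSR_COLLAGEN_PALETTE = ((200, 40, 35), (170, 30, 45), (215, 60, 60))
PSR_COUNTERSTAIN = (235, 220, 160)


def _tissue_footprint(height: int, width: int) -> np.ndarray:
    """Deterministic elliptical tissue footprint (boolean mask)."""
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2, (width - 1) / 2
    ry, rx = 0.38 * height, 0.38 * width
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _paint(
    footprint: np.ndarray,
    collagen_fraction: float,
    elastin_fraction: float,
    collagen_palette,
    elastin_palette,
    counterstain,
    background,
    rng,
) -> tuple[np.ndarray, float, float]:
    h, w = footprint.shape
    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = background
    tissue_idx = np.flatnonzero(footprint.ravel())
    n_tissue = tissue_idx.size
    rng.shuffle(tissue_idx)
    n_col = round(collagen_fraction * n_tissue)
    n_el = round(elastin_fraction * n_tissue)
    if n_col + n_el > n_tissue:
        n_el = n_tissue - n_col
    flat = img.reshape(-1, 3)
    flat[tissue_idx] = counterstain
    col_pal = np.asarray(collagen_palette, dtype=np.uint8)
    el_pal = np.asarray(elastin_palette, dtype=np.uint8)
    if n_col:
        flat[tissue_idx[:n_col]] = col_pal[rng.integers(0, len(col_pal), n_col)]
    if n_el:
        flat[tissue_idx[n_col : n_col + n_el]] = el_pal[
            rng.integers(0, len(el_pal), n_el)
        ]
    return img, n_col / n_tissue, n_el / n_tissue


def generate_vvg_image(
    width: int = 256,
    height: int = 256,
    collagen_fraction: float = 0.4,
    elastin_fraction: float = 0.3,
    seed: int = 0,
    sample_id: str = "synthetic",
) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """A Verhoeff-van Gieson-like section: painted pixel-exact stain fractions.

    An elliptical tissue region sits on a blank-slide background; within it,
    the requested fractions of pixels are painted with collagen-like
    (pink/magenta) and elastin-like (grey-to-black) hues, the rest with a
    neutral counterstain.  The returned ground truth records the *painted*
    fractions (requested fractions rounded to whole pixels).
    """
    if collagen_fraction < 0 or elastin_fraction < 0:
        raise ValueError("stain fractions must be non-negative")
    if collagen_fraction + elastin_fraction > 1:
        raise ValueError("collagen + elastin fractions must not exceed 1")
    rng = np.random.default_rng(seed)
    footprint = _tissue_footprint(height, width)
    img, f_col, f_el = _paint(
        footprint,
        collagen_fraction,
        elastin_fraction,
        VVG_COLLAGEN_PALETTE,
        VVG_ELASTIN_PALETTE,
        VVG_COUNTERSTAIN,
        VVG_BACKGROUND,
        rng,
    )
    truth = SyntheticGroundTruth(
        sample_id=sample_id,
        tissue_type="FL",
        patient_id=sample_id,
        true_collagen_fraction=f_col,
        true_elastin_fraction=f_el,
    )
    return img, truth


def generate_psr_image(
    vvg_truth: SyntheticGroundTruth,
    width: int = 256,
    height: int = 256,
    seed: int = 0,
    jitter: float = 0.01,
) -> np.ndarray:
    """The adjacent Picrosirius-Red section matching a VVG ground truth.

    Same tissue footprint; collagen painted in saturated red at the VVG
    collagen fraction perturbed by +/- ``jitter`` (uniform), emulating the
    section-to-section offset between adjacent cuts of the same block.
    """
    if vvg_truth.true_collagen_fraction is None:
        raise ValueError("vvg_truth must carry a painted collagen fraction")
    rng = np.random.default_rng(seed)
    frac = vvg_truth.true_collagen_fraction
    if jitter > 0:
        frac = float(np.clip(frac + rng.uniform(-jitter, jitter), 0.0, 1.0))
    footprint = _tissue_footprint(height, width)
    img, _, _ = _paint(
        footprint,
        frac,
        0.0,
        PSR_COLLAGEN_PALETTE,
        ((0, 0, 0),),  # unused: zero elastin
        PSR_COUNTERSTAIN,
        PSR_BACKGROUND,
        rng,
    )
    return img


# ---------------------------------------------------------------------------
# dataset writer


def write_dataset(
    out_dir,
    config: CohortConfig,
    n_bins: int = 1150,
    image_size: int = 160,
) -> dict:
    """Write a complete synthetic dataset (CSV tables, spectra, PNGs, ground truth).

    Returns a manifest dict mapping artifact names to paths.
    """
    from pathlib import Path

    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, _ = generate_feature_table(config)
    table.to_csv(out / "feature_table.csv", index=False)
    sset, truths = generate_spectrum_set(config, n_bins=n_bins)
    sset.intensities.to_csv(out / "spectra.csv")
    sset.labels.to_csv(out / "labels.csv", index=False)
    img_dir = out / "histology"
    img_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(config.seed + 7)
    gt_records = []
    for t in truths:
        if t.tissue_type != "FL":
            gt_records.append(t.to_dict())
            continue
        # collagen rises / elastin falls with subcluster index: degraded ECM
        col = float(np.clip(0.25 + 0.12 * (t.subcluster or 0) + rng.normal(0, 0.02), 0, 0.8))
        el = float(np.clip(0.45 - 0.10 * (t.subcluster or 0) + rng.normal(0, 0.02), 0, 1 - col))
        img_seed = int(rng.integers(0, 2**31 - 1))
        vvg, truth = generate_vvg_image(
            image_size, image_size, col, el, seed=img_seed, sample_id=t.sample_id
        )
        truth.subcluster = t.subcluster
        psr = generate_psr_image(truth, image_size, image_size, seed=img_seed + 1)
        Image.fromarray(vvg).save(img_dir / f"{t.sample_id}_vvg.png")
        Image.fromarray(psr).save(img_dir / f"{t.sample_id}_psr.png")
        gt_records.append(truth.to_dict())
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt_records, fh, indent=1)
    return {
        "feature_table": str(out / "feature_table.csv"),
        "spectra": str(out / "spectra.csv"),
        "labels": str(out / "labels.csv"),
        "histology_dir": str(img_dir),
        "ground_truth": str(out / "ground_truth.json"),
    }
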