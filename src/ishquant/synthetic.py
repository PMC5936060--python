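"""Synthetic fixtures: embryo-like ISH images, allele pairs, Ct tables.

Every downstream module can be exercised without any real data. Three
generators are provided:

* **Clutches of embryo images.** Each embryo is rendered as a light
  elliptical body on a lighter background with a dark horizontal stripe
  standing in for stained tissue (e.g. the dorsal aorta). Intensity
  truth is defined *post-inversion*: the stripe's inverted-scale mean
  intensity over the signal ROI is a draw from a truncated normal whose
  mean and coefficient of variation are set per genotype, so generator
  parameters live on the same scale as reported densitometry scores.
  Pixel noise and a horizontal illumination gradient are added on top;
  the gradient is parallel to the stripe and the background ROI sits
  directly above the signal ROI at the same x-span, so the gradient
  cancels in the background subtraction (as it should for a well-chosen
  background region).

* **Allele pairs for RFLP.** A random amplicon carrying exactly one
  restriction site placed to yield requested wild-type fragment lengths,
  plus a mutant allele in which a substitution or a k-bp deletion
  destroys the site without creating a new one. Both alleles are
  verified by digestion before being returned.

* **Single-embryo qPCR Ct tables** with housekeeping and target
  triplicates constructed so the embryo-level dCt is exactly
  Normal(mean, sd^2) (replicate noise is re-centred within each embryo).

Default clutch parameters follow a heterozygous-incross design: 1:2:1
Mendelian genotype ratio, group mean intensities 54 / 50.1 / 26.3 with
CVs 0.24 / 0.22 / 0.21 — dispersion typical of ISH densitometry.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .image_quant import Roi, invert, to_grayscale_8bit, write_image, write_roi_file
from .rflp import ENZYMES, NucleotideSequence, RestrictionEnzyme, digest, find_sites

__all__ = [
    "ClutchDesign",
    "TruthRecord",
    "GENOTYPES",
    "generate_embryo_image",
    "generate_clutch",
    "draw_score",
    "generate_allele_pair",
    "generate_qpcr_table",
]

GENOTYPES = ("WT", "HET", "MUT")


class GenerationError(RuntimeError):
    """Sequence construction failed after bounded retries."""


@dataclass(frozen=True)
class ClutchDesign:
    """Parameters of one simulated heterozygous-incross clutch.

    Intensity means are on the post-inversion 8-bit scale (0-255);
    ``cvs`` are coefficients of variation of the per-embryo true signal.
    ``noise_sd`` is per-pixel additive Gaussian noise; the illumination
    gradient ramps linearly left-to-right by ``gradient_amplitude``
    intensity units.
    """

    n_embryos: int = 130
    genotype_probabilities: tuple[float, float, float] = (0.25, 0.5, 0.25)
    means: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 54.0, "HET": 50.1, "MUT": 26.3}
    )
    cvs: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 0.24, "HET": 0.22, "MUT": 0.21}
    )
    noise_sd: float = 3.0
    gradient_amplitude: float = 10.0
    height: int = 128
    width: int = 192
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_embryos < 1:
            raise ValueError("need at least one embryo")
        if abs(sum(self.genotype_probabilities) - 1.0) > 1e-9:
            raise ValueError("genotype probabilities must sum to 1")
        if any(p < 0 for p in self.genotype_probabilities):
            raise ValueError("genotype probabilities must be non-negative")
        if any(self.means[g] < 0 for g in GENOTYPES):
            raise ValueError("mean intensities must be >= 0")
        if any(self.cvs[g] < 0 for g in GENOTYPES):
            raise ValueError("CVs must be >= 0")
        if self.height < 128 or self.width < 128:
            raise ValueError("image dimensions must be >= 128x128")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated embryo."""

    embryo_id: str
    true_genotype: str
    true_signal_intensity: float
    bands: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.true_genotype not in GENOTYPES:
            raise ValueError(f"invalid genotype {self.true_genotype!r}")


def draw_score(design: ClutchDesign, genotype: str, rng: np.random.Generator) -> float:
    """One per-embryo true signal intensity: Normal(mu, (cv*mu)^2), >= 0.

    The truncation at zero reflects that staining intensity cannot be
    negative; measured scores can still go negative through noise.
    """
    mu = design.means[genotype]
    sd = design.cvs[genotype] * mu
    if sd == 0:
        return mu
    a = (0.0 - mu) / sd
    return float(sps.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, random_state=rng))


# Geometry of the rendered embryo (fractions of image size). The stripe is
# the mock stained vessel; the background ROI sits directly above it with
# the same x-span so a horizontal gradient cancels in the subtraction.
_BODY_LEVEL = 60.0       # post-inversion intensity of unstained body
_STRIPE_HALF_H = 5       # stripe half-height, px
_ROI_MARGIN = 12         # px between signal and background ROI centres


def _stripe_geometry(h: int, w: int) -> tuple[int, int, int]:
    """(stripe row, ROI x0, ROI x1) for an image of size h x w."""
    return int(h * 0.62), int(w * 0.25), int(w * 0.75)


def generate_embryo_image(
    design: ClutchDesign,
    genotype: str,
    rng: np.random.Generator,
    embryo_id: str = "embryo",
) -> tuple[np.ndarray, Roi, Roi, TruthRecord]:
    """Render one embryo image plus its ROI pair and truth record.

    Returns the *pre-inversion* RGB image (as acquired by a camera: light
    background, dark stain) whose inverted 8-bit version reproduces the
    drawn intensity as the ROI score, up to noise and rounding.
    """
    h, w = design.height, design.width
    row, x0, x1 = _stripe_geometry(h, w)
    if not (0 < row - _ROI_MARGIN - _STRIPE_HALF_H and row + _STRIPE_HALF_H < h):
        raise ValueError("stripe or background ROI outside image bounds")

    intensity = draw_score(design, genotype, rng)

    # Build in post-inversion space: background ~0, body _BODY_LEVEL,
    # stripe _BODY_LEVEL + intensity.
    img = np.zeros((h, w), dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w]
    body = (
        ((xx - w / 2) / (w * 0.45)) ** 2 + ((yy - h / 2) / (h * 0.42)) ** 2
    ) <= 1.0
    img[body] = _BODY_LEVEL
    stripe = body & (np.abs(yy - row) <= _STRIPE_HALF_H)
    img[stripe] += intensity
    # Horizontal gradient: identical mean over any two ROIs sharing an
    # x-span, so it cancels in the background subtraction.
    img += design.gradient_amplitude * (xx / max(w - 1, 1))
    if design.noise_sd > 0:
        img += rng.normal(0.0, design.noise_sd, size=img.shape)
    inverted = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    # Camera view = photographic positive; stored as RGB.
    positive = invert(inverted)
    rgb = np.repeat(positive[:, :, None], 3, axis=2)

    signal = Roi(
        "signal",
        (
            (x0, row - _STRIPE_HALF_H),
            (x1, row - _STRIPE_HALF_H),
            (x1, row + _STRIPE_HALF_H),
            (x0, row + _STRIPE_HALF_H),
        ),
    )
    bg_row = row - _ROI_MARGIN - 2 * _STRIPE_HALF_H
    background = Roi(
        "background",
        tuple((x, y - (row - bg_row)) for x, y in signal.vertices),
    )
    truth = TruthRecord(embryo_id, genotype, intensity)
    return rgb, signal, background, truth


def generate_clutch(
    design: ClutchDesign,
    out_dir: str | Path | None = None,
    render_images: bool = True,
) -> pd.DataFrame:
    """Simulate a full clutch; optionally write images/ROIs/truth to disk.

    Genotypes are multinomial draws from the design probabilities. With
    ``out_dir`` set, writes one PNG per embryo, a combined ROI JSON file
    (rois.json) and a truth table (truth.csv). Returns the truth table
    with in-memory image/ROI objects attached; fully reproducible from
    ``design.seed`` (per-embryo sub-streams are spawned deterministically,
    so the truth table does not depend on whether images are rendered).
    ``render_images=False`` draws genotypes and true intensities only —
    useful for large statistical simulations where rendering dominates.
    """
    if design.n_embryos < 1:
        raise ValueError("need at least one embryo")
    if out_dir is not None and not render_images:
        raise ValueError("cannot write a dataset without rendering images")
    root = np.random.default_rng(design.seed)
    genotypes = root.choice(
        len(GENOTYPES), size=design.n_embryos, p=design.genotype_probabilities
    )
    child_seeds = root.integers(0, 2**31 - 1, size=design.n_embryos)

    rows, roi_records = [], []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for i, (g_idx, child_seed) in enumerate(zip(genotypes, child_seeds)):
        embryo_id = f"emb{i:04d}"
        genotype = GENOTYPES[g_idx]
        rng = np.random.default_rng(int(child_seed))
        if render_images:
            rgb, signal, background, truth = generate_embryo_image(
                design, genotype, rng, embryo_id
            )
        else:
            rgb = signal = background = None
            truth = TruthRecord(embryo_id, genotype, draw_score(design, genotype, rng))
        if out is not None:
            write_image(rgb, out / f"{embryo_id}.png")
            roi_records.append(
                {"embryo_id": embryo_id, "signal": signal, "background": background}
            )
        rows.append(
            {
                "embryo_id": embryo_id,
                "true_genotype": truth.true_genotype,
                "true_signal_intensity": truth.true_signal_intensity,
                "image": rgb,
                "signal_roi": signal,
                "background_roi": background,
            }
        )
    if out is not None:
        write_roi_file(roi_records, out / "rois.json")
        pd.DataFrame(rows)[
            ["embryo_id", "true_genotype", "true_signal_intensity"]
        ].to_csv(out / "truth.csv", index=False)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Allele construction for RFLP

def _random_site_instance(enzyme: RestrictionEnzyme, rng: np.random.Generator) -> str:
    from .rflp import IUPAC_CODES

    return "".join(
        rng.choice(sorted(IUPAC_CODES[c])) for c in enzyme.site
    )


def _random_bases(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def generate_allele_pair(
    total_length: int,
    enzyme: RestrictionEnzyme | str,
    cut_fragments: Sequence[int],
    mutation: str = "substitution",
    deletion_length: int = 5,
    seed: int | np.random.Generator = 0,
    max_tries: int = 200,
) -> tuple[NucleotideSequence, NucleotideSequence]:
    """Construct a wild-type / mutant amplicon pair for an RFLP assay.

    The wild-type allele has exactly one ``enzyme`` site, positioned so a
    complete digest yields ``cut_fragments`` (two lengths summing to
    ``total_length``). The mutant destroys the site by a single
    substitution (same length) or by a ``deletion_length``-bp deletion
    spanning the cut, creating no new site. Both alleles are verified by
    digestion; construction retries up to ``max_tries`` times before
    raising GenerationError.
    """
    enz = ENZYMES[enzyme] if isinstance(enzyme, str) else enzyme
    if len(cut_fragments) != 2:
        raise ValueError("exactly one site requested: give two fragment lengths")
    if sum(cut_fragments) != total_length:
        raise ValueError("cut_fragments must sum to total_length")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    cut_pos = int(cut_fragments[0])
    site_start = cut_pos - enz.cut_offset
    site_len = len(enz.site)
    if site_start < 0 or site_start + site_len > total_length:
        raise ValueError("site does not fit at the requested cut position")

    for _ in range(max_tries):
        site = _random_site_instance(enz, rng)
        bases = (
            _random_bases(site_start, rng)
            + site
            + _random_bases(total_length - site_start - site_len, rng)
        )
        if find_sites(bases, enz) != [cut_pos]:
            continue  # spurious extra site; retry

        if mutation == "substitution":
            mut_bases = _mutate_by_substitution(bases, site_start, site_len, enz, rng)
        elif mutation == "deletion":
            mut_bases = _mutate_by_deletion(
                bases, site_start, site_len, deletion_length, enz
            )
        else:
            raise ValueError("mutation must be 'substitution' or 'deletion'")
        if mut_bases is None:
            continue

        wt = NucleotideSequence("wt", bases)
        mut = NucleotideSequence("mut", mut_bases)
        # Verify by digesting both alleles.
        if digest(wt, enz).fragment_lengths != tuple(
            sorted((int(f) for f in cut_fragments), reverse=True)
        ):
            continue
        if digest(mut, enz).n_sites != 0:
            continue
        return wt, mut
    raise GenerationError(
        f"could not build a clean allele pair for {enz.name} in {max_tries} tries"
    )


def _mutate_by_substitution(
    bases: str,
    site_start: int,
    site_len: int,
    enz: RestrictionEnzyme,
    rng: np.random.Generator,
) -> str | None:
    """One base change inside the site that leaves no site anywhere."""
    positions = list(range(site_start, site_start + site_len))
    rng.shuffle(positions)
    for pos in positions:
        for new in "ACGT":
            if new == bases[pos]:
                continue
            cand = bases[:pos] + new + bases[pos + 1 :]
            if not find_sites(cand, enz):
                return cand
    return None


def _mutate_by_deletion(
    bases: str,
    site_start: int,
    site_len: int,
    k: int,
    enz: RestrictionEnzyme,
) -> str | None:
    """Delete k bases overlapping the site such that no site remains."""
    lo = max(0, site_start - k + 1)
    hi = min(len(bases) - k, site_start + site_len - 1)
    for start in range(lo, hi + 1):
        cand = bases[:start] + bases[start + k :]
        if not find_sites(cand, enz):
            return cand
    return None


# ---------------------------------------------------------------------------
# qPCR tables

def generate_qpcr_table(
    n_per_group: Mapping[str, int],
    delta_ct_means: Mapping[str, float],
    delta_ct_sds: Mapping[str, float],
    replicates_per_embryo: int = 3,
    target_gene: str = "runx1",
    housekeeping_gene: str = "eef1a1l1",
    housekeeping_mean_ct: float = 18.0,
    replicate_sd: float = 0.15,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a long-format single-embryo Ct table.

    Each embryo gets housekeeping and target replicate Cts whose means
    differ by a dCt drawn from Normal(mean, sd^2) for its group —
    replicate noise is re-centred so the embryo-level dCt equals the draw
    exactly (with sd=0 every embryo reproduces the group dCt). Groups are
    keyed by name (e.g. {'WT': 12, 'MUT': 12}).
    """
    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for group, n in n_per_group.items():
        if n < 2:
            raise ValueError("need n >= 2 per group")
        for _ in range(n):
            embryo_id = f"q{idx:03d}"
            idx += 1
            dct = rng.normal(delta_ct_means[group], delta_ct_sds[group])
            hk_center = rng.normal(housekeeping_mean_ct, 0.3)
            for gene, center in (
                (housekeeping_gene, hk_center),
                (target_gene, hk_center + dct),
            ):
                noise = rng.normal(0.0, replicate_sd, size=replicates_per_embryo)
                noise -= noise.mean()  # exact replicate mean = center
                cts = center + noise
                rows.append(
                    {
                        "embryo_id": embryo_id,
                        "gene": gene,
                        **{f"ct{i+1}": float(c) for i, c in enumerate(cts)},
                        "group": group,
                    }
                )
    return pd.DataFrame(rows)
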