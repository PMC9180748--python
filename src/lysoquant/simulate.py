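"""Seeded synthetic data with the statistical structure the pipeline assumes.

Three generators stand in for the study's inputs so every stage is
testable offline:

* :func:`gen_quant_dataset` — log-normal protein intensity matrices
  with planted group effects: log2 intensities are a per-protein
  baseline (uniform on [18, 30], spanning a realistic precursor-ion
  dynamic range) plus a ±``effect_log2`` shift in the non-reference
  group(s) for a planted fraction of proteins, plus Gaussian noise.
  Unique-peptide counts (1–10) and identification FDR (uniform on
  [0, 0.05]) emulate the search-engine columns the static filters act
  on, independently of any planted effect.
* :func:`gen_annotation_catalogs` — per-source membership driven by a
  latent "truly lysosomal" label: sensitivity for lysosomal proteins,
  false-positive rate otherwise; categorical sources pick a category
  uniformly among positives, Compartments draws confidences from
  [2.5, 5] for members and [0, 2] for non-members.
* :func:`gen_ld_image` — two-channel fields with anti-aliased bright
  disks (lipid droplets in channel 1, nuclei in channel 2, unit
  amplitude) plus additive Gaussian noise.

All generators are pure functions of their parameters and seed.
The planted ground truth travels alongside in :class:`SimTruth`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from lysoquant.quantio import (
    CRITERION_LAYERS,
    CRITERION_NAMES,
    AnnotationCatalog,
    QuantMatrix,
)

BASELINE_LOG2_RANGE = (18.0, 30.0)
PEPTIDE_RANGE = (1, 10)  # inclusive
ID_FDR_MAX = 0.05
COMPARTMENTS_MEMBER_RANGE = (2.5, 5.0)
COMPARTMENTS_NONMEMBER_RANGE = (0.0, 2.0)


@dataclass
class SimTruth:
    """Ground truth planted by the generators.

    ``dep_labels`` / ``lyso_labels`` map protein id → boolean;
    ``droplet_truth`` / ``nucleus_truth`` list planted ``(x, y,
    radius_um)`` disks; ``nuclei_overlap`` flags overlapping planted
    nuclei (permitted, but downstream counting may merge them).
    """

    dep_labels: dict[str, bool] = field(default_factory=dict)
    lyso_labels: dict[str, bool] = field(default_factory=dict)
    droplet_truth: list[tuple[float, float, float]] = field(default_factory=list)
    nucleus_truth: list[tuple[float, float, float]] = field(default_factory=list)
    nuclei_overlap: bool = False

    def __post_init__(self) -> None:
        for objs in (self.droplet_truth, self.nucleus_truth):
            for x, y, r in objs:
                if r <= 0:
                    raise ValueError(f"object radius must be > 0, got {r}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dep_labels": self.dep_labels,
            "lyso_labels": self.lyso_labels,
            "droplet_truth": [list(t) for t in self.droplet_truth],
            "nucleus_truth": [list(t) for t in self.nucleus_truth],
            "nuclei_overlap": self.nuclei_overlap,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            dep_labels={k: bool(v) for k, v in d.get("dep_labels", {}).items()},
            lyso_labels={k: bool(v) for k, v in d.get("lyso_labels", {}).items()},
            droplet_truth=[tuple(t) for t in d.get("droplet_truth", [])],
            nucleus_truth=[tuple(t) for t in d.get("nucleus_truth", [])],
            nuclei_overlap=bool(d.get("nuclei_overlap", False)),
        )


def gen_quant_dataset(
    n_proteins: int = 1000,
    groups: Sequence[str] = ("control", "case"),
    replicates_per_group: int = 3,
    frac_dep: float = 0.1,
    effect_log2: float = 1.0,
    noise_sigma_log2: float = 0.1,
    seed: int = 0,
) -> tuple[QuantMatrix, pd.DataFrame, SimTruth]:
    """Simulate a label-free quantitation table with planted DEPs.

    The first entry of ``groups`` is the reference; a planted protein
    is shifted by ±``effect_log2`` (sign random per protein) in every
    non-reference group.  Intensities are
    ``exp2(baseline + effect + N(0, noise_sigma_log2))``.
    """
    if n_proteins < 1:
        raise ValueError(f"n_proteins must be ≥ 1, got {n_proteins}")
    if len(groups) < 2:
        raise ValueError("need ≥ 2 groups")
    if len(set(groups)) != len(groups):
        raise ValueError("group labels must be unique")
    if replicates_per_group < 2:
        raise ValueError(f"replicates_per_group must be ≥ 2, got {replicates_per_group}")
    if not 0.0 <= frac_dep <= 1.0:
        raise ValueError(f"frac_dep must be in [0, 1], got {frac_dep}")
    if noise_sigma_log2 <= 0:
        raise ValueError(f"noise_sigma_log2 must be > 0, got {noise_sigma_log2}")

    rng = np.random.default_rng(seed)
    width = len(str(n_proteins))
    accessions = [f"SYN{str(i + 1).zfill(width)}" for i in range(n_proteins)]
    gene_symbols = [f"SGENE{str(i + 1).zfill(width)}" for i in range(n_proteins)]

    baseline = rng.uniform(*BASELINE_LOG2_RANGE, size=n_proteins)
    is_dep = rng.random(n_proteins) < frac_dep
    signs = rng.choice([-1.0, 1.0], size=n_proteins)
    effects = np.where(is_dep, signs * effect_log2, 0.0)

    sample_ids, group_of, columns = [], {}, []
    for gi, g in enumerate(groups):
        shift = effects if gi > 0 else np.zeros(n_proteins)
        for rep in range(replicates_per_group):
            sid = f"{g}_{rep + 1}"
            sample_ids.append(sid)
            group_of[sid] = g
            log2_int = baseline + shift + rng.normal(0, noise_sigma_log2, n_proteins)
            columns.append(np.exp2(log2_int))
    intensities = pd.DataFrame(
        np.column_stack(columns), index=accessions, columns=sample_ids
    )
    intensities.index.name = "accession"

    meta = pd.DataFrame(
        {
            "gene_symbol": gene_symbols,
            "unique_peptides": rng.integers(
                PEPTIDE_RANGE[0], PEPTIDE_RANGE[1] + 1, size=n_proteins
            ),
            "id_fdr": rng.uniform(0.0, ID_FDR_MAX, size=n_proteins),
        },
        index=pd.Index(accessions, name="accession"),
    )
    truth = SimTruth(dep_labels=dict(zip(accessions, map(bool, is_dep))))
    return QuantMatrix(intensities, group_of), meta, truth


def _rate_map(
    value: float | Mapping[str, float], sources: Sequence[str], what: str
) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = dict(value)
        unknown = set(out) - set(CRITERION_NAMES)
        if unknown:
            raise ValueError(f"unknown sources in {what}: {sorted(unknown)}")
        missing = [s for s in sources if s not in out]
        if missing:
            raise ValueError(f"{what} missing sources: {missing}")
    else:
        out = {s: float(value) for s in sources}
    for s, v in out.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{what}[{s!r}] = {v} outside [0, 1]")
    return out


def gen_annotation_catalogs(
    protein_ids: Sequence[str],
    p_lyso: float = 0.3,
    sensitivity_per_source: float | Mapping[str, float] = 0.9,
    fpr_per_source: float | Mapping[str, float] = 0.05,
    seed: int = 0,
    sources: Sequence[str] = CRITERION_NAMES,
) -> tuple[list[AnnotationCatalog], SimTruth]:
    """Simulate annotation catalogs around a latent lysosomal label.

    Each protein is lysosomal with probability ``p_lyso``; each source
    then reports it with probability sensitivity (if lysosomal) or FPR
    (otherwise).  Scalar rates apply to every source.
    """
    if not 0.0 <= p_lyso <= 1.0:
        raise ValueError(f"p_lyso must be in [0, 1], got {p_lyso}")
    unknown = set(sources) - set(CRITERION_NAMES)
    if unknown:
        raise ValueError(f"unknown sources: {sorted(unknown)}")
    sens = _rate_map(sensitivity_per_source, sources, "sensitivity_per_source")
    fpr = _rate_map(fpr_per_source, sources, "fpr_per_source")

    rng = np.random.default_rng(seed)
    ids = list(protein_ids)
    lyso = rng.random(len(ids)) < p_lyso

    catalogs = []
    for source in sources:
        member = np.where(lyso, rng.random(len(ids)) < sens[source],
                          rng.random(len(ids)) < fpr[source])
        entries: dict[str, object] = {}
        if source == "bovine":
            cats = rng.choice(["TrEMBL", "SwissProt"], size=len(ids))
            for pid, m, c in zip(ids, member, cats):
                if m:
                    entries[pid] = str(c)
        elif source == "rat":
            cats = rng.choice(["Misc", "EL"], size=len(ids))
            for pid, m, c in zip(ids, member, cats):
                if m:
                    entries[pid] = str(c)
        elif source == "compartments":
            conf_in = rng.uniform(*COMPARTMENTS_MEMBER_RANGE, size=len(ids))
            conf_out = rng.uniform(*COMPARTMENTS_NONMEMBER_RANGE, size=len(ids))
            for pid, m, ci, co in zip(ids, member, conf_in, conf_out):
                entries[pid] = float(ci if m else co)
        else:
            for pid, m in zip(ids, member):
                if m:
                    entries[pid] = True
        catalogs.append(
            AnnotationCatalog(
                source=source,
                layer=CRITERION_LAYERS[source],
                species="human",
                entries=entries,
            )
        )
    truth = SimTruth(lyso_labels=dict(zip(ids, map(bool, lyso))))
    return catalogs, truth


def _render_disks(
    shape: tuple[int, int],
    disks: Sequence[tuple[float, float, float]],
    pixel_size_um: float,
) -> np.ndarray:
    """Unit-amplitude anti-aliased disks; boundary pixels are coverage-weighted."""
    h, w = shape
    img = np.zeros(shape, dtype=np.float32)
    yy, xx = np.mgrid[:h, :w]
    for x_um, y_um, r_um in disks:
        cx, cy, r = x_um / pixel_size_um, y_um / pixel_size_um, r_um / pixel_size_um
        dist = np.hypot(xx - cx, yy - cy)
        img = np.maximum(img, np.clip(r - dist + 0.5, 0.0, 1.0).astype(np.float32))
    return img


def gen_ld_image(
    width_px: int = 512,
    height_px: int = 512,
    pixel_size_um: float = 0.1,
    droplets: Sequence[tuple[float, float, float]] = (),
    nuclei: Sequence[tuple[float, float, float]] = (),
    noise_sigma: float = 0.1,
    seed: int = 0,
) -> tuple["ImageSpec", SimTruth]:
    """Render a two-channel field with planted droplets and nuclei.

    Object coordinates and radii are in µm; every object must fit the
    frame.  Disk amplitude is 1.0, so ``1 / noise_sigma`` is the
    per-pixel SNR.  Overlapping nuclei are permitted but flagged.
    """
    from lysoquant.droplets import ImageSpec  # avoid import cycle at module load

    if width_px < 1 or height_px < 1:
        raise ValueError("image dimensions must be ≥ 1 pixel")
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be ≥ 0, got {noise_sigma}")

    w_um, h_um = width_px * pixel_size_um, height_px * pixel_size_um
    for name, objs in (("droplet", droplets), ("nucleus", nuclei)):
        for x, y, r in objs:
            if r <= 0:
                raise ValueError(f"{name} radius must be > 0, got {r}")
            if x - r < 0 or y - r < 0 or x + r > w_um or y + r > h_um:
                raise ValueError(
                    f"{name} at ({x}, {y}) µm radius {r} µm leaves the "
                    f"{w_um}×{h_um} µm frame"
                )

    overlap = False
    nuc = list(nuclei)
    for i in range(len(nuc)):
        for j in range(i + 1, len(nuc)):
            d = np.hypot(nuc[i][0] - nuc[j][0], nuc[i][1] - nuc[j][1])
            if d < nuc[i][2] + nuc[j][2]:
                overlap = True

    rng = np.random.default_rng(seed)
    shape = (height_px, width_px)
    ch1 = _render_disks(shape, droplets, pixel_size_um)
    ch2 = _render_disks(shape, nuclei, pixel_size_um)
    if noise_sigma > 0:
        ch1 = ch1 + rng.normal(0, noise_sigma, shape).astype(np.float32)
        ch2 = ch2 + rng.normal(0, noise_sigma, shape).astype(np.float32)

    truth = SimTruth(
        droplet_truth=[tuple(map(float, d)) for d in droplets],
        nucleus_truth=[tuple(map(float, n)) for n in nuc],
        nuclei_overlap=overlap,
    )
    return ImageSpec(ch1, ch2, pixel_size_um), truth


def write_ld_image(path: str | Path, image) -> None:
    """Write a two-channel image as a multi-channel 32-bit TIFF."""
    import tifffile

    stack = np.stack([image.droplet_channel, image.nucleus_channel]).astype(np.float32)
    tifffile.imwrite(
        path,
        stack,
        metadata={"axes": "CYX", "pixel_size_um": image.pixel_size_um},
    )


def read_ld_image(path: str | Path, pixel_size_um: float) -> "ImageSpec":
    """Read a two-channel TIFF (channel 0 droplets, channel 1 nuclei)."""
    import tifffile

    from lysoquant.droplets import ImageSpec

    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError(f"{path}: expected a multi-channel (C, Y, X) TIFF")
    return ImageSpec(
        np.asarray(stack[0], dtype=float),
        np.asarray(stack[1], dtype=float),
        pixel_size_um,
    )
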