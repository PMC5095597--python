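"""Synthetic phantom study generator.

Emulates a two-model (metastatic tumour / naive brain) protein phantom
study in which pH, protein content, and the water relaxation times are
serially varied — 26 phantoms per model, 52 in total — imaged with a
pulsed-train CEST protocol at 9.4 T plus inversion-recovery and spin-echo
relaxometry.

The mechanistic links from sample chemistry to spin-system parameters are
deliberately simple and isolated here:

* pH -> amine exchange rate: pure base catalysis, one decade per pH unit,
  anchored at pH 7.4.  The biggest modelling liberty in the package;
  acid- and water-catalysed terms are omitted.
* protein %w/v -> labile proton fractions: linear, anchored at 8% w/v.

Every dataset carries its generating ground truth, and regenerating from
the stored seed reproduces it bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import bloch
from .relaxometry import RelaxSeries
from .saturation import SaturationScheme, default_scheme
from .spinsystem import ExchangePool, InvalidInputError, SpinSystem
from .zspectrum import ZSpectrum

__all__ = [
    "PhantomSpec", "StudyDesign", "GroundTruth", "PhantomData", "StudyDataset",
    "ph_to_rate", "bsa_to_fraction", "build_design", "phantom_system",
    "realize_study", "render_image_stack", "roi_label_image",
]

#: amine exchange rate at the anchor pH 7.4, per phantom model (s^-1).
#: The tumour and brain extracts differ in their metabolite amine content,
#: so their pooled-average exchange rates differ.
K_REF = {"tumour": 1600.0, "brain": 2200.0}
ANCHOR_PH = 7.4
#: pH-independent exchange rate of the -3.5 ppm (aliphatic, NOE-mediated)
#: pool (s^-1).
K_NOE = 20.0
#: labile proton fractions at the 8% w/v anchor.
F_AMINE_8PCT = 2e-3
F_NOE_8PCT = 2e-3
ANCHOR_BSA = 8.0
#: fixed relaxation times of the labile pools (s).
POOL_RELAX = {"amine": (1.0, 0.01), "noe": (1.0, 0.005)}
#: baseline water relaxation with no added contrast agent, per model —
#: the two tissue extracts differ in composition and hence in their
#: intrinsic relaxation.
BASE_RELAX = {"tumour": (1.7, 0.14), "brain": (1.35, 0.10)}


def ph_to_rate(ph: float, pool: str = "amine", model: str = "tumour") -> float:
    """Exchange rate (s^-1) of a labile pool at the given pH.

    Amine protons are base-catalysed: one decade per pH unit, anchored at
    pH 7.4 with a model-specific reference rate.  The NOE-mediated pool is
    relayed through dipolar cross-relaxation and is pH independent.
    """
    if pool == "amine":
        if model not in K_REF:
            raise InvalidInputError(f"unknown phantom model {model!r}")
        return K_REF[model] * 10.0 ** (ph - ANCHOR_PH)
    if pool == "noe":
        return K_NOE
    raise InvalidInputError(f"unknown pool {pool!r}")


def bsa_to_fraction(bsa: float, pool: str = "amine") -> float:
    """Labile proton fraction at the given protein concentration (%w/v).

    Linear in protein content, anchored at 8% w/v.
    """
    if pool == "amine":
        return F_AMINE_8PCT * bsa / ANCHOR_BSA
    if pool == "noe":
        return F_NOE_8PCT * bsa / ANCHOR_BSA
    raise InvalidInputError(f"unknown pool {pool!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """One phantom's composition and water relaxation."""

    id: str
    model: str
    ph: float
    bsa: float
    t1_water: float
    t2_water: float
    varied_parameter: str

    def __post_init__(self) -> None:
        if not (5.5 <= self.ph <= 8.5):
            raise InvalidInputError("ph outside [5.5, 8.5]")
        if self.bsa <= 0 or self.t1_water <= 0 or self.t2_water <= 0:
            raise InvalidInputError("bsa, t1_water and t2_water must be > 0")
        if self.model not in ("tumour", "brain"):
            raise InvalidInputError(f"unknown model {self.model!r}")
        if self.varied_parameter not in ("ph", "bsa", "t1", "t2"):
            raise InvalidInputError("varied_parameter must be ph|bsa|t1|t2")


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters stored with every synthetic dataset."""

    amine_rate: float
    amine_fraction: float
    noe_rate: float
    noe_fraction: float
    t1_water: float
    t2_water: float

    @property
    def amine_flux(self) -> float:
        """Rate x fraction product of the amine pool."""
        return self.amine_rate * self.amine_fraction


@dataclass(frozen=True)
class StudyDesign:
    """Full factorial layout of the synthetic study."""

    phantoms: tuple[PhantomSpec, ...]
    scheme: SaturationScheme
    noise_sd: float = 0.005
    relax_noise: float = 0.01
    n_voxels: int = 21
    matrix_size: int = 32
    roi_radius: float = 2.5

    def per_model(self, model: str) -> tuple[PhantomSpec, ...]:
        return tuple(p for p in self.phantoms if p.model == model)

    def arm(self, model: str, varied: str) -> tuple[PhantomSpec, ...]:
        return tuple(p for p in self.phantoms
                     if p.model == model and p.varied_parameter == varied)


# serial variation ranges: (parameter, low, high, count)
_ARMS = (
    ("ph", 6.0, 7.6, 6),
    ("bsa", 4.0, 16.0, 7),
    ("t1", 0.3, 1.7, 7),
    ("t2", 0.029, 0.140, 6),
)


#: fractional drag of the non-target relaxation time when a contrast
#: agent sweeps the target over its full arm: gadolinium added to vary T1
#: also shortens T2 by up to 34%, iron particles added to vary T2 also
#: shorten T1 by up to 18%.
CROSS_EFFECT = {"t1": 0.34, "t2": 0.18}


def build_design(noise_sd: float = 0.005, n_voxels: int = 21,
                 scheme: SaturationScheme | None = None,
                 relax_noise: float = 0.01,
                 cross_effect: bool = False) -> StudyDesign:
    """The 52-phantom factorial design: per model, four serial-variation
    arms (pH 6.0-7.6 n=6; protein 4-16% w/v n=7; T1 0.3-1.7 s n=7;
    T2 29-140 ms n=6), each parameter evenly spaced and the others at
    baseline (pH 7.4, 8% w/v, model-specific no-contrast-agent
    relaxation).

    ``cross_effect=True`` additionally drags the non-target relaxation
    time along the contrast-agent arms (see ``CROSS_EFFECT``); the
    default treats the relaxation times as independently varied, the
    usual approximation when the target change is at least twice the
    collateral one.
    """
    if scheme is None:
        scheme = default_scheme()
    phantoms = []
    for model in ("tumour", "brain"):
        base_t1, base_t2 = BASE_RELAX[model]
        for varied, lo, hi, n in _ARMS:
            for i, value in enumerate(np.linspace(lo, hi, n)):
                base = {"ph": ANCHOR_PH, "bsa": ANCHOR_BSA,
                        "t1": base_t1, "t2": base_t2}
                base[varied] = float(value)
                if cross_effect and varied in CROSS_EFFECT:
                    # agent load grows toward the short-relaxation end
                    load = (hi - value) / (hi - lo)
                    other = "t2" if varied == "t1" else "t1"
                    base[other] *= 1.0 - CROSS_EFFECT[varied] * load
                phantoms.append(PhantomSpec(
                    id=f"{model}-{varied}-{i:02d}", model=model,
                    ph=base["ph"], bsa=base["bsa"],
                    t1_water=base["t1"], t2_water=base["t2"],
                    varied_parameter=varied))
    return StudyDesign(phantoms=tuple(phantoms), scheme=scheme,
                       noise_sd=noise_sd, n_voxels=n_voxels,
                       relax_noise=relax_noise)


def phantom_system(spec: PhantomSpec, larmor: float = 400.0) -> SpinSystem:
    """Three-pool spin system realizing one phantom."""
    water = ExchangePool("water", 0.0, 0.0, 1.0, spec.t1_water, spec.t2_water)
    pools = [water]
    for name, offset in (("amine", 2.8), ("noe", -3.5)):
        t1p, t2p = POOL_RELAX[name]
        pools.append(ExchangePool(
            name, offset, ph_to_rate(spec.ph, name, spec.model),
            bsa_to_fraction(spec.bsa, name), t1p, t2p))
    return SpinSystem(tuple(pools), larmor)


def ground_truth(spec: PhantomSpec) -> GroundTruth:
    return GroundTruth(
        amine_rate=ph_to_rate(spec.ph, "amine", spec.model),
        amine_fraction=bsa_to_fraction(spec.bsa, "amine"),
        noe_rate=K_NOE, noe_fraction=bsa_to_fraction(spec.bsa, "noe"),
        t1_water=spec.t1_water, t2_water=spec.t2_water)


#: relaxometry timing grids: nine inversion times from 13.14 ms to 8 s
#: (log-spaced) and ten echo times from 30 to 160 ms (linear).
IR_TIMES = tuple(np.geomspace(0.01314, 8.0, 9))
SE_TIMES = tuple(np.linspace(0.030, 0.160, 10))


@dataclass
class PhantomData:
    """Everything generated for one phantom."""

    spec: PhantomSpec
    truth: GroundTruth
    clean_spectrum: ZSpectrum          # noise-free, per-phantom
    voxel_signals: np.ndarray          # (n_voxels, n_offsets), noisy
    voxel_z0: np.ndarray               # (n_voxels,), noisy references
    ir_series: RelaxSeries
    se_series: RelaxSeries

    def roi_mean_spectrum(self) -> ZSpectrum:
        """ROI-mean spectrum (voxel average), the model-fitting input."""
        return ZSpectrum(
            offsets=self.clean_spectrum.offsets.copy(),
            signals=np.clip(self.voxel_signals.mean(axis=0), -0.05, 1.05),
            z0=float(self.voxel_z0.mean()))

    def voxel_spectrum(self, i: int) -> ZSpectrum:
        return ZSpectrum(
            offsets=self.clean_spectrum.offsets.copy(),
            signals=np.clip(self.voxel_signals[i], -0.05, 1.05),
            z0=max(float(self.voxel_z0[i]), 1e-6))


@dataclass
class StudyDataset:
    design: StudyDesign
    seed: int
    phantoms: list  # of PhantomData

    def phantom(self, phantom_id: str) -> PhantomData:
        for p in self.phantoms:
            if p.spec.id == phantom_id:
                return p
        raise KeyError(phantom_id)


def realize_study(design: StudyDesign, seed: int = 0) -> StudyDataset:
    """Generate the full synthetic dataset for a design.

    Per phantom: the noise-free Z spectrum (one simulation per offset from
    thermal equilibrium, acquisition-grade pulse discretization), ROI voxel
    realizations with additive Gaussian noise of sd ``design.noise_sd`` on
    normalized Z (references included), and relaxometry series with
    fractional Gaussian noise ``design.relax_noise``.  A single seeded RNG
    drives all noise, so identical (design, seed) pairs give identical
    datasets.
    """
    rng = np.random.default_rng(seed)
    phantoms = []
    for spec in design.phantoms:
        system = phantom_system(spec)
        clean = bloch.simulate_zspectrum(system, design.scheme)
        n_off = clean.offsets.size
        nv = design.n_voxels
        voxel_signals = clean.signals[None, :] + rng.normal(
            0.0, design.noise_sd, (nv, n_off))
        voxel_z0 = clean.z0 + rng.normal(
            0.0, design.noise_sd, nv)

        ti = np.asarray(IR_TIMES)
        ir_clean = 1.0 - 2.0 * np.exp(-ti / spec.t1_water)
        ir = np.abs(ir_clean + rng.normal(0.0, design.relax_noise, ti.size))
        te = np.asarray(SE_TIMES)
        se_clean = np.exp(-te / spec.t2_water)
        se = np.abs(se_clean + rng.normal(0.0, design.relax_noise, te.size))

        phantoms.append(PhantomData(
            spec=spec, truth=ground_truth(spec), clean_spectrum=clean,
            voxel_signals=voxel_signals, voxel_z0=voxel_z0,
            ir_series=RelaxSeries("inversion_recovery", ti, ir),
            se_series=RelaxSeries("spin_echo", te, np.maximum(se, 1e-6))))
    return StudyDataset(design=design, seed=seed, phantoms=phantoms)


def roi_label_image(design: StudyDesign, n_phantoms: int = 26) -> np.ndarray:
    """Integer label image (matrix_size^2) with one disc ROI per phantom.

    Discs are laid out on a grid; label 0 is background, labels 1..n mark
    the phantoms of one acquisition (26 imaged simultaneously).
    """
    m = design.matrix_size
    labels = np.zeros((m, m), dtype=int)
    cols = 5
    rows = int(np.ceil(n_phantoms / cols))
    yy, xx = np.mgrid[0:m, 0:m]
    for i in range(n_phantoms):
        r, c = divmod(i, cols)
        cy = (r + 0.5) * m / rows
        cx = (c + 0.5) * m / cols
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= design.roi_radius ** 2
        labels[mask] = i + 1
    return labels


def render_image_stack(dataset: StudyDataset, model: str = "tumour",
                       seed: int | None = None):
    """Per-offset image stack for the 26 phantoms of one model.

    Returns (stack, labels): stack has shape (n_offsets+2, m, m) — the
    sampled offsets followed by the two reference acquisitions — with
    independent voxel noise inside each disc ROI.
    """
    design = dataset.design
    phantoms = [p for p in dataset.phantoms if p.spec.model == model]
    labels = roi_label_image(design, len(phantoms))
    m = design.matrix_size
    n_off = phantoms[0].clean_spectrum.offsets.size
    rng = np.random.default_rng(dataset.seed + 1 if seed is None else seed)
    stack = np.zeros((n_off + 2, m, m))
    for i, p in enumerate(phantoms):
        mask = labels == i + 1
        nv = int(mask.sum())
        clean = np.concatenate([p.clean_spectrum.signals,
                                [p.clean_spectrum.z0, p.clean_spectrum.z0]])
        stack[:, mask] = clean[:, None] + rng.normal(
            0.0, design.noise_sd, (n_off + 2, nv))
    return stack, labels
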