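"""Synthetic three-species dataset generator.

Produces measurement tables (lognormal variation with species-specific
means and allometric slopes), 2-D landmark configurations (species mean
shape plus isotropic noise under a random similarity transform) and
fixed-length DNA alignments (species-fixed diagnostic substitutions plus
within-species polymorphism with a given transition/transversion odds).
All draws are deterministic functions of the scenario seed, with one
independent stream per artifact and species, so adding a species never
perturbs another species' data.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .barcode import NUCLEOTIDES, AlignedSequences
from .errors import ValidationError
from .gma import LandmarkDataset
from .measurements import CHARACTERS, ID_COLUMNS

SIGMA_RESID = 0.05          # residual SD of log-measurements
TRANSLATION_BOX = 5.0       # landmark translations drawn from [-box, box]^2
SCALE_RANGE = (0.5, 2.0)    # landmark scale drawn log-uniformly from this range

_STREAM_MEASUREMENTS = 1
_STREAM_LANDMARKS = 2
_STREAM_SEQUENCES = 3

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def load_default_ancestor() -> str:
    """The 557-nt ancestor sequence bundled with the package."""
    text = resources.files("cryptax.data").joinpath("ancestor_coi.fasta").read_text()
    return "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))


@dataclass
class SpeciesModel:
    """Ground-truth generative model for one species."""

    name: str
    mu_log: np.ndarray            # (25,) mean log-measurements
    allometric_slope: np.ndarray  # (25,) slopes on log-size
    size_sd: float                # SD of specimen log-size
    mean_shape: np.ndarray        # (7, 2) landmark mean configuration
    diag_positions: dict[int, str] = field(default_factory=dict)  # 0-based
    poly_rate: float = 0.0
    kappa: float = 2.0

    def __post_init__(self) -> None:
        self.mu_log = np.asarray(self.mu_log, dtype=float)
        self.allometric_slope = np.asarray(self.allometric_slope, dtype=float)
        self.mean_shape = np.asarray(self.mean_shape, dtype=float)
        if self.mu_log.shape != (len(CHARACTERS),):
            raise ValidationError(f"{self.name}: mu_log must have length {len(CHARACTERS)}")
        if self.allometric_slope.shape != (len(CHARACTERS),):
            raise ValidationError(f"{self.name}: allometric_slope length mismatch")
        if not (np.isfinite(self.mu_log).all() and np.isfinite(self.allometric_slope).all()):
            raise ValidationError(f"{self.name}: non-finite model parameters")
        if not np.isfinite(self.size_sd) or self.size_sd < 0:
            raise ValidationError(f"{self.name}: size_sd must be finite and >= 0")
        if self.mean_shape.shape[1] != 2:
            raise ValidationError(f"{self.name}: mean_shape must be k x 2")
        centered = self.mean_shape - self.mean_shape.mean(axis=0)
        if (centered**2).sum() <= 0:
            raise ValidationError(f"{self.name}: degenerate mean shape")
        if not 0.0 <= self.poly_rate <= 1.0:
            raise ValidationError(f"{self.name}: poly_rate must be in [0, 1]")
        if not self.kappa > 0:
            raise ValidationError(f"{self.name}: kappa must be > 0")
        for pos, state in self.diag_positions.items():
            if state not in NUCLEOTIDES:
                raise ValidationError(f"{self.name}: bad diagnostic state {state!r} at {pos}")


@dataclass
class Scenario:
    """A full synthetic-data scenario with planted ground truth."""

    species: list[SpeciesModel]
    n_per_species: list[int]
    ancestor_seq: str
    seed: int = 0
    sigma_resid: float = SIGMA_RESID

    def __post_init__(self) -> None:
        if len(self.species) != len(self.n_per_species):
            raise ValidationError("species and n_per_species differ in length")
        if any(n < 2 for n in self.n_per_species):
            raise ValidationError("n_per_species must be >= 2 (pairs needed downstream)")
        self.ancestor_seq = self.ancestor_seq.upper()
        if set(self.ancestor_seq) - set(NUCLEOTIDES):
            raise ValidationError("ancestor_seq must be over {A,C,G,T}")
        L = len(self.ancestor_seq)
        claimed: dict[tuple[int, str], str] = {}
        for model in self.species:
            for pos, state in model.diag_positions.items():
                if not 0 <= pos < L:
                    raise ValidationError(
                        f"{model.name}: diagnostic position {pos} outside alignment 0..{L-1}"
                    )
                prior = claimed.get((pos, state))
                if prior is not None:
                    raise ValidationError(
                        f"conflicting diagnostic state {state!r} at position {pos} "
                        f"planted for both {prior!r} and {model.name!r}"
                    )
                claimed[(pos, state)] = model.name
        names = [m.name for m in self.species]
        if len(set(names)) != len(names):
            raise ValidationError("species names must be unique")

    @property
    def length(self) -> int:
        return len(self.ancestor_seq)

    def specimen_ids(self, species_index: int) -> list[str]:
        name = self.species[species_index].name
        return [f"{name}_{i:03d}" for i in range(self.n_per_species[species_index])]

    def partition(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for si, model in enumerate(self.species):
            for sid in self.specimen_ids(si):
                out[sid] = model.name
        return out

    def _rng(self, stream: int, species_index: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(stream, species_index))
        )


def gen_measurements(scenario: Scenario) -> pd.DataFrame:
    """Generate the specimen x 25-character measurement table.

    Per specimen: log-size ``s ~ N(0, size_sd)``; character c takes the
    value ``exp(mu_log[c] + slope[c] * s + eps)``, eps ~ N(0, sigma_resid).
    """
    frames = []
    for si, model in enumerate(scenario.species):
        n = scenario.n_per_species[si]
        rng = scenario._rng(_STREAM_MEASUREMENTS, si)
        sizes = rng.normal(0.0, model.size_sd, size=n) if model.size_sd > 0 else np.zeros(n)
        eps = (
            rng.normal(0.0, scenario.sigma_resid, size=(n, len(CHARACTERS)))
            if scenario.sigma_resid > 0
            else np.zeros((n, len(CHARACTERS)))
        )
        logs = model.mu_log[None, :] + sizes[:, None] * model.allometric_slope[None, :] + eps
        frame = pd.DataFrame(np.exp(logs), columns=list(CHARACTERS))
        frame.insert(0, "species", model.name)
        frame.insert(0, "specimen_id", scenario.specimen_ids(si))
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)[[*ID_COLUMNS, *CHARACTERS]]


def gen_landmarks(scenario: Scenario, noise_sd: float = 0.02) -> LandmarkDataset:
    """Generate landmark configurations under random similarity transforms.

    Each configuration is the species mean shape plus iid isotropic
    Gaussian noise, then rotated (angle uniform on [0, 2pi)), scaled
    (log-uniform on [0.5, 2]) and translated (uniform in a fixed box).
    The nuisance parameters are recorded in ``dataset.nuisance``.
    """
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    ids: list[str] = []
    species: list[str] = []
    coords: list[np.ndarray] = []
    nuisance_rows = []
    for si, model in enumerate(scenario.species):
        rng = scenario._rng(_STREAM_LANDMARKS, si)
        k = model.mean_shape.shape[0]
        for sid in scenario.specimen_ids(si):
            config = model.mean_shape + rng.normal(0.0, noise_sd, size=(k, 2))
            theta = rng.uniform(0.0, 2.0 * np.pi)
            scale = np.exp(rng.uniform(np.log(SCALE_RANGE[0]), np.log(SCALE_RANGE[1])))
            shift = rng.uniform(-TRANSLATION_BOX, TRANSLATION_BOX, size=2)
            c, s = np.cos(theta), np.sin(theta)
            rot = np.array([[c, -s], [s, c]])
            transformed = scale * (config @ rot.T) + shift
            ids.append(sid)
            species.append(model.name)
            coords.append(transformed)
            nuisance_rows.append(
                {"specimen_id": sid, "theta": theta, "scale": scale,
                 "shift_x": shift[0], "shift_y": shift[1]}
            )
    dataset = LandmarkDataset(ids, species, np.stack(coords))
    dataset.nuisance = pd.DataFrame(nuisance_rows)  # test introspection only
    return dataset


def gen_sequences(scenario: Scenario) -> tuple[AlignedSequences, dict[str, str]]:
    """Generate the DNA alignment and its specimen->species partition.

    Each specimen starts from the ancestor, receives its species' fixed
    diagnostic substitutions, and every remaining site independently
    mutates with probability ``poly_rate``; a mutation is a transition
    with odds kappa:1, else one of the two transversions equiprobably.
    """
    ancestor = np.array(list(scenario.ancestor_seq))
    ids: list[str] = []
    seqs: list[str] = []
    for si, model in enumerate(scenario.species):
        rng = scenario._rng(_STREAM_SEQUENCES, si)
        diag_idx = np.array(sorted(model.diag_positions), dtype=int)
        mutable = np.ones(scenario.length, dtype=bool)
        if diag_idx.size:
            mutable[diag_idx] = False
        for sid in scenario.specimen_ids(si):
            seq = ancestor.copy()
            for pos in diag_idx:
                seq[pos] = model.diag_positions[int(pos)]
            if model.poly_rate > 0:
                hits = np.flatnonzero(mutable & (rng.random(scenario.length) < model.poly_rate))
                for pos in hits:
                    base = seq[pos]
                    if rng.random() < model.kappa / (model.kappa + 1.0):
                        seq[pos] = _TRANSITION[base]
                    else:
                        seq[pos] = _TRANSVERSIONS[base][rng.integers(0, 2)]
            ids.append(sid)
            seqs.append("".join(seq))
    return AlignedSequences(ids, seqs), scenario.partition()


# ---------------------------------------------------------------------------
# the bundled default scenario

def _wing_shape(rng: np.random.Generator, jitter: float = 0.0) -> np.ndarray:
    """A 7-landmark wing-like outline, optionally perturbed."""
    base = np.array(
        [
            [0.00, 0.00],   # base of leading-edge vein
            [1.10, 0.18],   # vein junction
            [1.90, 0.22],   # distal vein junction
            [2.35, 0.18],   # distal vein tip
            [2.05, 0.02],   # short vein tip
            [2.70, -0.45],  # wing tip
            [1.20, -0.85],  # posterior margin tip
        ]
    )
    if jitter > 0:
        base = base + rng.normal(0.0, jitter, size=base.shape)
    return base


def default_scenario(seed: int = 0, n_per_species: int = 12) -> Scenario:
    """Three species with planted measurement, shape and sequence structure.

    Species B and C carry opposite shifts on the F5W and OV characters
    relative to A (a strong planted F5W/OV discriminating ratio), mildly
    distinct allometric slopes and wing shapes, and disjoint sets of
    species-fixed diagnostic substitutions.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0,)))
    ancestor = load_default_ancestor()
    L = len(ancestor)
    p = len(CHARACTERS)

    mu_base = np.log(np.linspace(0.08, 0.60, p))
    idx = {c: i for i, c in enumerate(CHARACTERS)}

    def shifted(pairs: dict[str, float]) -> np.ndarray:
        mu = mu_base.copy()
        for char, delta in pairs.items():
            mu[idx[char]] += delta
        return mu

    slopes_a = np.ones(p)
    slopes_b = np.ones(p)
    slopes_b[idx["OV"]] = 1.35  # planted positive allometry
    slopes_c = np.ones(p)
    slopes_c[idx["SL"]] = 0.70

    n_diag = {0: 20, 1: 14, 2: 16}
    positions = rng.permutation(L)[: sum(n_diag.values())]
    diag_maps: list[dict[int, str]] = []
    offset = 0
    for si in range(3):
        block = positions[offset : offset + n_diag[si]]
        offset += n_diag[si]
        diag = {}
        for pos in block:
            choices = [b for b in NUCLEOTIDES if b != ancestor[pos]]
            diag[int(pos)] = choices[int(rng.integers(0, 3))]
        diag_maps.append(diag)

    shape_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, 1)))
    shapes = [_wing_shape(shape_rng, jitter=0.0)]
    for _ in range(2):
        shapes.append(_wing_shape(shape_rng, jitter=0.06))

    models = [
        SpeciesModel(
            name="sp_A",
            mu_log=mu_base,
            allometric_slope=slopes_a,
            size_sd=0.06,
            mean_shape=shapes[0],
            diag_positions=diag_maps[0],
            poly_rate=0.003,
            kappa=4.0,
        ),
        SpeciesModel(
            name="sp_B",
            mu_log=shifted({"F5W": 0.18, "OV": -0.18}),
            allometric_slope=slopes_b,
            size_sd=0.06,
            mean_shape=shapes[1],
            diag_positions=diag_maps[1],
            poly_rate=0.003,
            kappa=4.0,
        ),
        SpeciesModel(
            name="sp_C",
            mu_log=shifted({"F2L": 0.16, "PVL": -0.16, "F5W": -0.10}),
            allometric_slope=slopes_c,
            size_sd=0.06,
            mean_shape=shapes[2],
            diag_positions=diag_maps[2],
            poly_rate=0.003,
            kappa=4.0,
        ),
    ]
    return Scenario(
        species=models,
        n_per_species=[n_per_species] * 3,
        ancestor_seq=ancestor,
        seed=seed,
    )
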