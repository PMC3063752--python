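"""Species classification, observables, rendering, scenarios and manifests.

Species names follow the polymerase nomenclature: an Rp specialised on RNA
templates is an RNA replicase (RdRp), an Rp specialised on DNA templates a
transcriptase (DdRp), a Dp on DNA templates a DNA replicase (DdDp), a Dp on
RNA templates a reverse transcriptase (RdDp); polymerases recognising both
template types well are dual-specificity, and parasites are a role of their
own regardless of their (inert) recognition parameters.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .compartment_cpm import CPMParams
from .reaction_core import ConfigurationError, Form, KineticParams, Role
from .surface_ca import Grid, PopulationSpec, SurfaceScenario

__all__ = [
    "SpeciesThresholds",
    "SPECIES_NAMES",
    "classify_species",
    "classify_array",
    "histogram2d_recognition",
    "render_snapshot",
    "snapshot_census",
    "RunManifest",
    "ScenarioConfig",
    "load_scenario",
    "list_scenarios",
    "neutral_trait_drift",
]

SPECIES_NAMES = ["RNA_replicase", "transcriptase", "dual_Rp",
                 "DNA_replicase", "reverse_transcriptase", "dual_Dp",
                 "parasite"]


@dataclass(frozen=True)
class SpeciesThresholds:
    """Cut points on the recognition parameters.

    ``high`` separates dual-specificity polymerases (both parameters >=
    high) from specialists; ``low`` marks a clearly negligible recognition
    of the other template type.  Molecules between the cuts are assigned to
    the nearest specialist class by comparing the two parameters (the
    documented nearest-class rule).
    """

    low: float = 0.2
    high: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.low < self.high <= 1):
            raise ConfigurationError("need 0 <= low < high <= 1")


def classify_species(role: Role, rrec: float, drec: float,
                     thresholds: Optional[SpeciesThresholds] = None) -> str:
    """Total classification of a catalyst or parasite into a species name."""
    th = thresholds or SpeciesThresholds()
    if role == Role.parasite:
        return "parasite"
    dual = rrec >= th.high and drec >= th.high
    if role == Role.Rp:
        if dual:
            return "dual_Rp"
        if drec < th.low and rrec >= th.low:
            return "RNA_replicase"
        if rrec < th.low and drec >= th.low:
            return "transcriptase"
        return "RNA_replicase" if rrec >= drec else "transcriptase"
    if dual:
        return "dual_Dp"
    if rrec < th.low and drec >= th.low:
        return "DNA_replicase"
    if drec < th.low and rrec >= th.low:
        return "reverse_transcriptase"
    return "DNA_replicase" if drec >= rrec else "reverse_transcriptase"


def classify_array(grid: Grid,
                   thresholds: Optional[SpeciesThresholds] = None
                   ) -> tuple[np.ndarray, list[str]]:
    """Vectorised classification; empty squares get code -1."""
    th = thresholds or SpeciesThresholds()
    codes = np.full(grid.n_sites, -1, dtype=np.int8)
    rr, dd = grid.rrec, grid.drec
    dual = (rr >= th.high) & (dd >= th.high)
    rp = grid.kind == int(Role.Rp)
    dp = grid.kind == int(Role.Dp)
    rna_side = ((dd < th.low) & (rr >= th.low)) | \
        ((~((rr < th.low) & (dd >= th.low))) & (rr >= dd))
    codes[rp & dual] = SPECIES_NAMES.index("dual_Rp")
    codes[rp & ~dual & rna_side] = SPECIES_NAMES.index("RNA_replicase")
    codes[rp & ~dual & ~rna_side] = SPECIES_NAMES.index("transcriptase")
    dna_side = ((rr < th.low) & (dd >= th.low)) | \
        ((~((dd < th.low) & (rr >= th.low))) & (dd >= rr))
    codes[dp & dual] = SPECIES_NAMES.index("dual_Dp")
    codes[dp & ~dual & dna_side] = SPECIES_NAMES.index("DNA_replicase")
    codes[dp & ~dual & ~dna_side] = \
        SPECIES_NAMES.index("reverse_transcriptase")
    codes[grid.kind == int(Role.parasite)] = SPECIES_NAMES.index("parasite")
    return codes, SPECIES_NAMES


def histogram2d_recognition(grid_or_values, bins: int = 50
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram of (rrec, drec) over [0,1]^2; counts sum to N."""
    if isinstance(grid_or_values, Grid):
        occ = (grid_or_values.kind != 0) \
            & (grid_or_values.kind != int(Role.parasite))
        rr = grid_or_values.rrec[occ]
        dd = grid_or_values.drec[occ]
    else:
        rr, dd = grid_or_values
        rr = np.asarray(rr)
        dd = np.asarray(dd)
    edges = np.linspace(0.0, 1.0, bins + 1)
    counts, xe, ye = np.histogram2d(rr, dd, bins=(edges, edges))
    return counts, xe, ye


# deterministic palette; black background is "empty"
SPECIES_PALETTE: dict[str, tuple[int, int, int]] = {
    "RNA_replicase": (230, 60, 40),
    "transcriptase": (60, 140, 240),
    "dual_Rp": (240, 170, 40),
    "DNA_replicase": (40, 190, 90),
    "reverse_transcriptase": (170, 70, 220),
    "dual_Dp": (40, 220, 220),
    "parasite": (230, 230, 230),
}
_EMPTY_RGB = (0, 0, 0)


def render_snapshot(grid: Grid, coloring: str = "species", block: int = 1,
                    thresholds: Optional[SpeciesThresholds] = None):
    """Render the lattice to a PIL image, one pixel block per square.

    ``coloring``: ``species`` (fixed palette, invertible), ``drec_value``
    (viridis over the DNA-recognition parameter) or ``compartment``
    (deterministic id-hashed colours, medium black).
    """
    from PIL import Image

    h, w = grid.height, grid.width
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    if coloring == "species":
        codes, names = classify_array(grid, thresholds)
        codes2 = codes.reshape(h, w)
        for idx, name in enumerate(names):
            rgb[codes2 == idx] = SPECIES_PALETTE[name]
    elif coloring == "drec_value":
        from matplotlib import cm

        occ = (grid.kind != 0).reshape(h, w)
        vals = cm.viridis(grid.drec.reshape(h, w))[:, :, :3]
        rgb[occ] = (vals[occ] * 255).astype(np.uint8)
    elif coloring == "compartment":
        ids = grid.comp.reshape(h, w).astype(np.int64)
        rng_cols = ((ids * 2654435761) % 255).astype(np.uint8)
        rgb[..., 0] = np.where(ids > 0, 55 + rng_cols % 200, 0)
        rgb[..., 1] = np.where(ids > 0, 55 + (ids * 40503 % 251) % 200, 0)
        rgb[..., 2] = np.where(ids > 0, 55 + (ids * 9176 % 241) % 200, 0)
    else:
        raise ConfigurationError(f"unknown coloring {coloring!r}")
    img = Image.fromarray(rgb, mode="RGB")
    if block > 1:
        img = img.resize((w * block, h * block), Image.NEAREST)
    img.info["legend"] = json.dumps({"coloring": coloring,
                                     "palette": SPECIES_PALETTE})
    return img


def snapshot_census(img) -> dict[str, int]:
    """Invert a species-coloured snapshot back into per-species counts."""
    arr = np.asarray(img)
    inverse = {rgb: name for name, rgb in SPECIES_PALETTE.items()}
    counts = {name: 0 for name in SPECIES_PALETTE}
    colors, n = np.unique(arr.reshape(-1, 3), axis=0, return_counts=True)
    for rgb, c in zip(map(tuple, colors), n):
        if rgb in inverse:
            counts[inverse[rgb]] = int(c)
    return counts


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit for bit."""

    scenario: str
    seed: int
    params: dict
    code_version: str = __version__
    extra: dict = field(default_factory=dict)
    started: str = ""
    finished: str = ""
    termination: str = ""

    def start(self) -> "RunManifest":
        self.started = datetime.datetime.now().isoformat(timespec="seconds")
        return self

    def finish(self, reason: str = "completed") -> "RunManifest":
        self.finished = datetime.datetime.now().isoformat(timespec="seconds")
        self.termination = reason
        return self

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @staticmethod
    def read(path) -> "RunManifest":
        return RunManifest(**json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# scenario presets
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    name: str
    engine: str                      # "surface" | "compartment"
    scenario: SurfaceScenario
    cpm: Optional[CPMParams] = None
    compartment_layout: Optional[dict] = None
    notes: str = ""

    def manifest(self) -> RunManifest:
        params = dataclasses.asdict(self.scenario.params)
        params.update({
            "width": self.scenario.width, "height": self.scenario.height,
            "density": self.scenario.density,
            "wellmixed": self.scenario.wellmixed,
            "rt_suppressed": self.scenario.rt_suppressed,
        })
        if self.cpm is not None:
            params["cpm"] = dataclasses.asdict(self.cpm)
        return RunManifest(scenario=self.name, seed=self.scenario.seed,
                           params=params)


def _spec(role, form, rrec, drec, fraction):
    return PopulationSpec(Role[role] if isinstance(role, str) else role,
                          Form[form] if isinstance(form, str) else form,
                          rrec, drec, fraction)


_EVOLVING = dict(mu_r=0.01, mu_d=0.01, delta=0.05)
# The wave-pattern experiments (self-replicators + parasites) and the
# transcription-system experiments persist at desk scales in different
# corners of the (decay, diffusion) plane; each preset family carries its
# calibrated pair (see docs/methods.md).
_WAVE = dict(d_rna=0.05, d_dna=0.05, diff=0.01)
_TRANS = dict(d_rna=0.02, d_dna=0.02, diff=0.1)

IDEAL_SELFREP = (0.4, 0.0)        # idealized pure self-replication values
IDEAL_TRANSCRIPTION = (0.0, 1.0)  # idealized pure transcription values
IDEAL_TRANSLIKE_RP = (1.0, 1.0)   # dual-specificity Rp of the
IDEAL_TRANSLIKE_DP = (0.0, 1.0)   # transcription-like system


def _surface_std(seed: int, size: Optional[int]) -> ScenarioConfig:
    n = size or 1024
    params = KineticParams(mu_par=1e-4, mu_rp_to_dp=1e-4, **_EVOLVING,
                           **_WAVE)
    comp = [_spec("Rp", "RNA", 0.9, 0.5, 1.0)]
    return ScenarioConfig(
        "surface_std", "surface",
        SurfaceScenario(n, n, 0.3, comp, params, seed=seed),
        notes="standard surface run (parasites arise by mutation); enable "
              "mu_rp_to_dp only after the Rp-only equilibrium if staging "
              "the two-phase protocol")


def _surface_pure_transcription(seed, size):
    n = size or 512
    params = KineticParams(mu_par=1e-5, **_TRANS)
    rr, dd = IDEAL_TRANSCRIPTION
    comp = [_spec("Rp", "RNA", rr, dd, 0.25), _spec("Rp", "DNA", rr, dd, .25),
            _spec("Dp", "RNA", rr, dd, 0.25), _spec("Dp", "DNA", rr, dd, .25)]
    return ScenarioConfig(
        "surface_pure_transcription", "surface",
        SurfaceScenario(n, n, 0.3, comp, params, seed=seed),
        notes="idealized transcription system, mutations off except the "
              "parasite channel")


def _surface_coexistence(seed, size):
    """Self-replication band next to a transcription band; the evolved
    equilibrium community of the standard run, set up directly."""
    n = size or 512
    params = KineticParams(mu_par=1e-5, **_TRANS)
    rr, dd = IDEAL_TRANSCRIPTION
    selfrep = [_spec("Rp", "RNA", 0.9, 0.0, 1.0)]
    trans = [_spec("Rp", "RNA", rr, dd, 0.25),
             _spec("Rp", "DNA", rr, dd, 0.25),
             _spec("Dp", "RNA", rr, dd, 0.25),
             _spec("Dp", "DNA", rr, dd, 0.25)]
    return ScenarioConfig(
        "surface_coexistence", "surface",
        SurfaceScenario(n, n, 0.3, [], params, seed=seed,
                        bands=[selfrep, trans]),
        notes="RNA replicase + transcription system + mutational parasite "
              "influx; substrate for the descent protocol")


def _surface_remove_selfrep(seed, size):
    n = size or 512
    params = KineticParams(mu_par=1e-5, mu_rp_to_dp=1e-4, **_EVOLVING,
                           **_TRANS)
    rr, dd = IDEAL_TRANSCRIPTION
    comp = [_spec("Rp", "RNA", rr, dd, 0.22), _spec("Rp", "DNA", rr, dd, .22),
            _spec("Dp", "RNA", rr, dd, 0.22), _spec("Dp", "DNA", rr, dd, .22),
            _spec("parasite", "RNA", 0, 0, 0.12)]
    return ScenarioConfig(
        "surface_remove_selfrep", "surface",
        SurfaceScenario(n, n, 0.3, comp, params, seed=seed),
        notes="transcription system + parasites with the self-replication "
              "system removed; watch the transcriptase re-evolve RNA "
              "replication")


def _surface_no_predefined_parasite(seed, size):
    n = size or 512
    params = KineticParams(mu_rp_to_dp=1e-4, **_EVOLVING, **_WAVE)
    comp = [_spec("Rp", "RNA", 0.9, 0.5, 1.0)]
    return ScenarioConfig(
        "surface_no_predefined_parasite", "surface",
        SurfaceScenario(n, n, 0.3, comp, params, seed=seed),
        notes="catalyst/parasite distinction left continuous")


def _surface_no_complex(seed, size):
    n = size or 512
    params = KineticParams(mu_par=1e-4, mu_rp_to_dp=1e-4,
                           complex_formation_enabled=False, **_EVOLVING,
                           **_WAVE)
    comp = [_spec("Rp", "RNA", 0.9, 0.5, 1.0)]
    return ScenarioConfig(
        "surface_no_complex", "surface",
        SurfaceScenario(n, n, 0.3, comp, params, seed=seed),
        notes="instantaneous-replication control")


def _compartment(seed, size, rt_suppressed=False, name="compartment_std"):
    n = size or 512
    params = KineticParams(diff=1.0, mu_par=1e-4, mu_rp_to_dp=1e-4,
                           **_EVOLVING)
    comp = [_spec("Rp", "RNA", 0.9, 0.5, 1.0)]
    sc = SurfaceScenario(n, n, 0.0, comp, params, seed=seed,
                         rt_suppressed=rt_suppressed)
    layout = {"radius": 10, "fill_density": 0.5,
              "spacing": 32, "composition": comp}
    return ScenarioConfig(name, "compartment", sc, cpm=CPMParams(),
                          compartment_layout=layout,
                          notes="compartment model; diffusion raised so the "
                                "interior is relatively well-mixed")


def _wellmixed(seed, size, which):
    n = size or 512
    params = KineticParams(**_EVOLVING)
    rpr, rpd = IDEAL_TRANSLIKE_RP
    dpr, dpd = IDEAL_TRANSLIKE_DP
    if which == "selfrep":
        comp = [_spec("Rp", "RNA", rpr, rpd, 1.0)]
    elif which == "translike":
        comp = [_spec("Rp", "RNA", rpr, rpd, 0.25),
                _spec("Rp", "DNA", rpr, rpd, 0.25),
                _spec("Dp", "RNA", dpr, dpd, 0.25),
                _spec("Dp", "DNA", dpr, dpd, 0.25)]
    elif which == "translike_rt":
        comp = [_spec("Rp", "RNA", rpr, rpd, 0.25),
                _spec("Rp", "DNA", rpr, rpd, 0.25),
                _spec("Dp", "RNA", 1.0, dpd, 0.25),
                _spec("Dp", "DNA", 1.0, dpd, 0.25)]
    elif which == "translike_nodna":
        comp = [_spec("Rp", "RNA", rpr, rpd, 1 / 3),
                _spec("Rp", "DNA", rpr, rpd, 1 / 3),
                _spec("Dp", "RNA", dpr, dpd, 1 / 3)]
    else:   # pragma: no cover - guarded by PRESETS keys
        raise ConfigurationError(which)
    return ScenarioConfig(
        f"wellmixed_{which}", "surface",
        SurfaceScenario(n, n, 0.3, comp, params, seed=seed, wellmixed=True,
                        rt_suppressed=(which == "translike_nodna")),
        notes="global interactions (well-mixed), diffusion disabled")


def _fixed_boundary_fitness(seed, size):
    cfg = _compartment(seed, size, name="fixed_boundary_fitness")
    cfg.cpm = CPMParams(frozen_boundaries=True)
    cfg.notes = ("compartment fitness assay: boundaries immobilised at the "
                 "division-threshold size, mutations off; fill with either "
                 "the transcription-like system or Rp^RNA alone")
    cfg.scenario.params = KineticParams(diff=1.0)
    return cfg


PRESETS = {
    "surface_std": _surface_std,
    "surface_pure_transcription": _surface_pure_transcription,
    "surface_coexistence": _surface_coexistence,
    "surface_remove_selfrep": _surface_remove_selfrep,
    "surface_no_predefined_parasite": _surface_no_predefined_parasite,
    "surface_no_complex": _surface_no_complex,
    "compartment_std": lambda seed, size: _compartment(seed, size),
    "compartment_no_rt": lambda seed, size: _compartment(
        seed, size, rt_suppressed=True, name="compartment_no_rt"),
    "wellmixed_selfrep": lambda s, n: _wellmixed(s, n, "selfrep"),
    "wellmixed_translike": lambda s, n: _wellmixed(s, n, "translike"),
    "wellmixed_translike_rt": lambda s, n: _wellmixed(s, n, "translike_rt"),
    "wellmixed_translike_nodna":
        lambda s, n: _wellmixed(s, n, "translike_nodna"),
    "fixed_boundary_fitness": _fixed_boundary_fitness,
}


def list_scenarios() -> list[str]:
    return sorted(PRESETS)


def load_scenario(name_or_path, seed: int = 0,
                  size: Optional[int] = None) -> ScenarioConfig:
    """Load a named preset or a TOML/JSON configuration file.

    File format: top-level ``engine``, ``width``, ``height``, ``density``,
    ``seed``, ``wellmixed``; a ``[kinetics]`` table with
    :class:`KineticParams` fields; a ``[[population]]`` array with
    ``role``/``form``/``rrec``/``drec``/``fraction``; optional ``[cpm]``.
    Malformed files raise a :class:`ConfigurationError` naming the offending
    field.
    """
    name = str(name_or_path)
    if name in PRESETS:
        return PRESETS[name](seed, size)
    path = Path(name_or_path)
    if not path.exists():
        raise ConfigurationError(
            f"unknown scenario {name!r}; presets: {', '.join(list_scenarios())}")
    if path.suffix == ".json":
        raw = json.loads(path.read_text())
    else:
        import tomllib

        raw = tomllib.loads(path.read_text())
    try:
        kin = KineticParams(**raw.get("kinetics", {}))
    except TypeError as e:
        raise ConfigurationError(f"bad [kinetics] field: {e}") from e
    pops = []
    for i, p in enumerate(raw.get("population", [])):
        try:
            pops.append(_spec(p["role"], p["form"], p["rrec"], p["drec"],
                              p["fraction"]))
        except KeyError as e:
            raise ConfigurationError(
                f"population entry {i} missing field {e}") from e
    try:
        sc = SurfaceScenario(
            width=raw["width"], height=raw["height"],
            density=raw["density"], composition=pops, params=kin,
            seed=raw.get("seed", seed),
            wellmixed=raw.get("wellmixed", False),
            neighborhood=raw.get("neighborhood", "moore"),
            rt_suppressed=raw.get("rt_suppressed", False))
    except KeyError as e:
        raise ConfigurationError(f"missing required field {e}") from e
    cpm = None
    if "cpm" in raw:
        try:
            cpm = CPMParams(**raw["cpm"])
        except TypeError as e:
            raise ConfigurationError(f"bad [cpm] field: {e}") from e
    return ScenarioConfig(name=path.stem,
                          engine=raw.get("engine", "surface"),
                          scenario=sc, cpm=cpm)


# ---------------------------------------------------------------------------
# neutral reference process
# ---------------------------------------------------------------------------

def neutral_trait_drift(n: int, v0: float, mu: float, delta: float,
                        turnover: float, times: Sequence[float],
                        rng: np.random.Generator) -> np.ndarray:
    """Mutation-only null for a bounded trait under birth-death turnover.

    A population of ``n`` trait values starts at ``v0``; individuals are
    replaced at per-capita rate ``turnover`` by a copy of a random survivor,
    mutated with probability ``mu`` by a uniform step of half-width
    ``delta`` clamped to [0, 1].  No trait value affects any rate, so the
    trajectory of the population mean is the no-selection reference against
    which an observed decline is judged.  Returns the mean-trait trajectory
    sampled at ``times``.
    """
    v = np.full(n, float(v0))
    out = np.empty(len(times))
    t = 0.0
    ti = 0
    rate = turnover * n
    while ti < len(times):
        dt = rng.exponential(1.0 / rate)
        if t + dt > times[ti]:
            out[ti] = v.mean()
            ti += 1
            if ti >= len(times):
                break
            # do not consume the event; re-check against the next time
            continue
        t += dt
        dead = rng.integers(n)
        parent = rng.integers(n)
        val = v[parent]
        if rng.random() < mu:
            val = float(np.clip(val + rng.uniform(-delta, delta), 0.0, 1.0))
        v[dead] = val
    return out
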