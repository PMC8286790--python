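"""Run configuration: TOML parsing, validation and the pipeline driver.

A run config wires together the sensor stack, particle model, detection
spot, mass-conversion constant and a list of peptide measurements.  Each
measurement supplies its steady-state responses either directly in degrees
or as sensorgram files plus a plateau window.  ``validate_config`` collects
*all* problems (with key paths) before failing, so a bad file is diagnosed
in one pass.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from sprquant import __version__ as _version
from sprquant.errors import ConfigError
from sprquant.geometry import (
    DEFAULT_AREA_PACKING_FRACTION,
    DEFAULT_VOLUME_FILL_FACTOR,
    PackingParameters,
    ParticleModel,
    RodDimensions,
)
from sprquant.optics import SensorStack
from sprquant.quantify import (
    DEFAULT_MASS_CONVERSION,
    DEFAULT_SPOT_DIAMETER_MM,
    DetectionSpot,
    MassConversionConstant,
    MeasurementRecord,
    PeptideSpec,
    QuantificationResult,
    run_chain,
)
from sprquant.sensorgram import (
    read_sensorgram,
    reference_subtract,
    steady_state_response,
)

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib


@dataclass(frozen=True)
class MeasurementEntry:
    """One peptide measurement: plateau degrees or sensorgram files."""

    peptide: PeptideSpec
    immobilization_deg: float
    binding_deg: Optional[float] = None
    active_file: Optional[Path] = None
    reference_file: Optional[Path] = None
    window_s: Optional[tuple[float, float]] = None
    concentration_um: float = 100.0

    @property
    def uses_files(self) -> bool:
        return self.active_file is not None


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved, validated pipeline configuration."""

    stack: SensorStack
    particle: ParticleModel
    spot: DetectionSpot
    k: MassConversionConstant
    measurements: tuple[MeasurementEntry, ...]
    seed: int = 0
    output_dir: Path = Path("results")
    source: Optional[Path] = None
    raw: dict = field(default_factory=dict)


def _check_positive(errors: list[str], table: dict, key_path: str, key: str, value):
    if not isinstance(value, (int, float)) or not value > 0:
        errors.append(f"{key_path}.{key}: must be a positive number, got {value!r}")
        return False
    return True


def validate_config(path: str | Path) -> RunConfig:
    """Parse and validate a run config, reporting every failure at once."""
    path = Path(path)
    try:
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
    except FileNotFoundError:
        raise ConfigError([f"{path}: file not found"])
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError([f"{path}: TOML parse error: {exc}"])

    errors: list[str] = []
    base = path.parent

    # --- sensor stack -----------------------------------------------------
    stack = None
    stack_tbl = doc.get("stack", {})
    stack_file = stack_tbl.get("file")
    if stack_file is not None:
        stack_path = base / stack_file
        if not stack_path.exists():
            errors.append(f"stack.file: {stack_path} does not exist")
        else:
            try:
                stack = SensorStack.from_toml(stack_path)
            except Exception as exc:
                errors.append(f"stack.file: {exc}")
    else:
        stack = SensorStack.default()

    # --- particle model ---------------------------------------------------
    p_tbl = doc.get("particle", {})
    packing_fraction = p_tbl.get("packing_fraction", DEFAULT_AREA_PACKING_FRACTION)
    fill_factor = p_tbl.get("fill_factor", DEFAULT_VOLUME_FILL_FACTOR)
    refractive_index = p_tbl.get("refractive_index", 1.35)
    particle = None
    try:
        packing = PackingParameters(
            area_packing_fraction=packing_fraction, volume_fill_factor=fill_factor
        )
        if "volume_um3" in p_tbl:
            particle = ParticleModel(
                volume_um3=p_tbl["volume_um3"],
                refractive_index=refractive_index,
                packing=packing,
            )
        elif "length_um" in p_tbl and "width_um" in p_tbl:
            particle = ParticleModel.from_rod(
                RodDimensions(p_tbl["length_um"], p_tbl["width_um"]),
                shape_model=p_tbl.get("shape_model", "spherocylinder"),
                refractive_index=refractive_index,
                packing=packing,
            )
        else:
            particle = ParticleModel.bcg_default()
    except Exception as exc:
        errors.append(f"particle: {exc}")

    # --- spot / conversion ------------------------------------------------
    spot_diameter = doc.get("spot", {}).get("diameter_mm", DEFAULT_SPOT_DIAMETER_MM)
    spot = None
    if _check_positive(errors, doc, "spot", "diameter_mm", spot_diameter):
        spot = DetectionSpot(diameter_mm=spot_diameter)
    k_value = doc.get("conversion", {}).get("k_ng_per_cm2_deg", DEFAULT_MASS_CONVERSION)
    k = None
    if _check_positive(errors, doc, "conversion", "k_ng_per_cm2_deg", k_value):
        k = MassConversionConstant(k=k_value)

    # --- measurements -----------------------------------------------------
    entries: list[MeasurementEntry] = []
    raw_measurements = doc.get("measurements", [])
    if not raw_measurements:
        errors.append("measurements: at least one [[measurements]] entry is required")
    names_seen: set[str] = set()
    for i, m in enumerate(raw_measurements):
        kp = f"measurements[{i}]"
        name = m.get("name")
        if not name:
            errors.append(f"{kp}.name: required")
            name = f"<entry {i}>"
        if name in names_seen:
            errors.append(f"{kp}.name: duplicate peptide name {name!r}")
        names_seen.add(name)
        mw = m.get("molecular_weight")
        if not isinstance(mw, (int, float)) or not mw > 0:
            errors.append(
                f"{kp}.molecular_weight: must be a positive number, got {mw!r}"
            )
            continue
        anchor = m.get("anchor", "none")
        if anchor not in ("polyK", "CPP", "none"):
            errors.append(f"{kp}.anchor: must be polyK, CPP or none, got {anchor!r}")
            continue
        immob = m.get("immobilization_deg")
        if not isinstance(immob, (int, float)) or immob < 0:
            errors.append(
                f"{kp}.immobilization_deg: must be a number >= 0, got {immob!r}"
            )
            continue
        binding = m.get("binding_deg")
        active_file = m.get("active_file")
        window = m.get("window")
        if binding is None and active_file is None:
            errors.append(f"{kp}: needs either binding_deg or active_file")
            continue
        if binding is not None and (not isinstance(binding, (int, float)) or binding < 0):
            errors.append(f"{kp}.binding_deg: must be a number >= 0, got {binding!r}")
            continue
        active_path = reference_path = None
        window_t = None
        if active_file is not None:
            active_path = base / active_file
            if not active_path.exists():
                errors.append(f"{kp}.active_file: {active_path} does not exist")
            ref_file = m.get("reference_file")
            if ref_file is not None:
                reference_path = base / ref_file
                if not reference_path.exists():
                    errors.append(f"{kp}.reference_file: {reference_path} does not exist")
            if not (
                isinstance(window, (list, tuple))
                and len(window) == 2
                and all(isinstance(v, (int, float)) for v in window)
                and window[0] < window[1]
            ):
                errors.append(
                    f"{kp}.window: need [t0, t1] with t0 < t1 when using files"
                )
            else:
                window_t = (float(window[0]), float(window[1]))
        entries.append(
            MeasurementEntry(
                peptide=PeptideSpec(name=str(name), molecular_weight=mw, anchor=anchor),
                immobilization_deg=float(immob),
                binding_deg=None if binding is None else float(binding),
                active_file=active_path,
                reference_file=reference_path,
                window_s=window_t,
                concentration_um=float(m.get("concentration_um", 100.0)),
            )
        )

    seed = doc.get("seed", 0)
    if not isinstance(seed, int):
        errors.append(f"seed: must be an integer, got {seed!r}")
        seed = 0

    if errors:
        raise ConfigError(errors)
    assert stack is not None and particle is not None
    assert spot is not None and k is not None
    return RunConfig(
        stack=stack,
        particle=particle,
        spot=spot,
        k=k,
        measurements=tuple(entries),
        seed=seed,
        output_dir=Path(doc.get("output_dir", "results")),
        source=path,
        raw=doc,
    )


@dataclass(frozen=True)
class RunReport:
    """Machine-readable pipeline output: rows plus every intermediate."""

    version: str
    intermediates: dict
    rows: tuple[QuantificationResult, ...]
    binding_sources: tuple[str, ...]
    warnings: tuple[str, ...]
    config_echo: dict

    def to_dict(self) -> dict:
        return {
            "software_version": self.version,
            "intermediates": self.intermediates,
            "results": [
                {
                    "peptide": r.peptide,
                    "coverage_fraction": r.coverage_fraction,
                    "coverage_percent": 100.0 * r.coverage_fraction,
                    "particle_count": r.particle_count,
                    "particle_count_rounded": r.particle_count_rounded,
                    "mass_per_area_ng_cm2": r.mass_per_area_ng_cm2,
                    "total_mass_ng": r.total_mass_ng,
                    "molecule_count": r.molecule_count,
                    "molecules_per_particle": r.molecules_per_particle,
                    "binding_source": src,
                }
                for r, src in zip(self.rows, self.binding_sources)
            ],
            "warnings": list(self.warnings),
            "config": self.config_echo,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, default=str) + "\n"

    def to_tsv(self) -> str:
        header = (
            "peptide\tcoverage_percent\tparticles\tmass_per_area_ng_cm2\t"
            "total_mass_ng\tmolecules\tmolecules_per_particle"
        )
        lines = [header]
        for r in self.rows:
            lines.append(
                f"{r.peptide}\t{100.0 * r.coverage_fraction:.6g}\t"
                f"{r.particle_count_rounded}\t{r.mass_per_area_ng_cm2:.6g}\t"
                f"{r.total_mass_ng:.6g}\t{r.molecule_count:.6g}\t"
                f"{r.molecules_per_particle:.6g}"
            )
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> tuple[Path, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tsv = outdir / "report.tsv"
        js = outdir / "report.json"
        tsv.write_text(self.to_tsv())
        js.write_text(self.to_json())
        return tsv, js


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline for a validated config."""
    from sprquant.optics import max_monolayer_response

    warnings: list[str] = []
    particle = config.particle

    try:
        max_deg = max_monolayer_response(config.stack, particle)
    except Exception as exc:
        raise RuntimeError(f"[optics] full-monolayer modeling failed: {exc}") from exc

    intermediates = {
        "wavelength_nm": config.stack.wavelength_nm,
        "particle_volume_um3": particle.volume_um3,
        "equivalent_diameter_nm": particle.equivalent_diameter_nm,
        "effective_layer_thickness_nm": particle.effective_layer_thickness_nm,
        "footprint_area_nm2": particle.footprint_area_nm2,
        "spot_diameter_mm": config.spot.diameter_mm,
        "spot_area_nm2": config.spot.area_nm2,
        "spot_area_cm2": config.spot.area_cm2,
        "max_monolayer_response_deg": max_deg,
        "mass_conversion_ng_cm2_per_deg": config.k.k,
    }

    rows: list[QuantificationResult] = []
    sources: list[str] = []
    for entry in config.measurements:
        if entry.uses_files:
            binding_deg, source = _binding_from_files(entry, warnings)
        else:
            binding_deg = entry.binding_deg
            source = "direct"
        if binding_deg == 0:
            warnings.append(f"{entry.peptide.name}: zero binding response")
        record = MeasurementRecord(
            peptide=entry.peptide,
            immobilization_response=entry.immobilization_deg,
            binding_response=binding_deg,
            analyte_concentration_um=entry.concentration_um,
            reference_corrected=source != "direct-uncorrected",
        )
        try:
            rows.append(
                run_chain(
                    record,
                    particle,
                    spot=config.spot,
                    k=config.k,
                    max_monolayer_deg=max_deg,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"[quantify] {entry.peptide.name}: {exc}") from exc
        sources.append(source)

    return RunReport(
        version=_version,
        intermediates=intermediates,
        rows=tuple(rows),
        binding_sources=tuple(sources),
        warnings=tuple(warnings),
        config_echo=config.raw,
    )


def _binding_from_files(entry: MeasurementEntry, warnings: list[str]):
    active = read_sensorgram(entry.active_file)
    if entry.reference_file is not None:
        reference = read_sensorgram(entry.reference_file)
        corrected = reference_subtract(active, reference)
        source = "sensorgram-reference-corrected"
    else:
        corrected = active
        source = "sensorgram-uncorrected"
        warnings.append(
            f"{entry.peptide.name}: no reference channel; using raw active plateau"
        )
    plateau = steady_state_response(corrected, entry.window_s)
    if plateau.mean_deg < 0:
        warnings.append(
            f"{entry.peptide.name}: negative plateau {plateau.mean_deg:.4g} deg "
            "clipped to 0"
        )
        return 0.0, source
    return plateau.mean_deg, source
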