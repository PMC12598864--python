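"""Readers, writers and table renderers.

Solvent records come from a flat YAML document (one solvent per file) or a
delimited table (CSV/TSV); molecule topologies from delimited site tables.
The typographic minus variants common in typeset tables (en dash, true
minus) are accepted on input; machine-readable output always uses the
ASCII hyphen.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cycles import CycleReport
from .fepmc import FEPResult, RigidMolecule, SiteParams
from .thermochem import GasSpecies, Quantity, SolventSpec

__all__ = [
    "normalize_minus",
    "read_solvent_yaml",
    "read_solvent_table",
    "write_solvent_table",
    "read_gas_table",
    "read_molecule_csv",
    "packaged_path",
    "render_table1",
    "render_table3_experimental",
    "reports_to_frame",
    "fep_log_frame",
    "RunConfig",
]

_MINUS_VARIANTS = str.maketrans({"−": "-", "–": "-", "—": "-"})


def normalize_minus(text: str) -> str:
    """Map en dash / em dash / true minus glyphs to the ASCII hyphen."""
    return text.translate(_MINUS_VARIANTS)


def packaged_path(name: str) -> Path:
    """Path to a data file shipped with the package."""
    return Path(str(resources.files("pkasolv.data").joinpath(name)))


def _opt_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, str):
        value = normalize_minus(value).strip()
        if not value:
            return None
    f = float(value)
    return None if math.isnan(f) else f


_Q_FIELDS = ("dG_gas_acid", "dG_gas_base", "dG_sol_SH", "dG_sol_H")


def _spec_from_mapping(row: Mapping) -> SolventSpec:
    kwargs = {}
    for fname in _Q_FIELDS:
        kwargs[fname] = Quantity(
            _opt_float(row[fname]), _opt_float(row.get(f"{fname}_sigma")), "kcal/mol"
        )
    return SolventSpec(
        name=str(row["name"]),
        conc_SH=_opt_float(row["conc_SH"]),
        pK_ap=Quantity(_opt_float(row["pK_ap"]), _opt_float(row.get("pK_ap_sigma"))),
        delta=Quantity(_opt_float(row.get("delta", 0.0)) or 0.0),
        T=_opt_float(row.get("T", 298.15)) or 298.15,
        **kwargs,
    )


def read_solvent_yaml(path: str | Path) -> SolventSpec:
    """One solvent record from a flat key-value YAML document."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a mapping document")
    return _spec_from_mapping(doc)


def _read_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    text = normalize_minus(Path(path).read_text())
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return pd.read_csv(
        _io.StringIO(text), comment="#", sep=sep, float_precision="round_trip"
    )


def read_solvent_table(path: str | Path) -> dict[str, SolventSpec]:
    """Solvent records from a delimited table, keyed by name."""
    df = _read_table(path)
    out: dict[str, SolventSpec] = {}
    for _, row in df.iterrows():
        spec = _spec_from_mapping(row.to_dict())
        out[spec.name] = spec
    return out


def write_solvent_table(specs: Iterable[SolventSpec], path: str | Path) -> None:
    """Write solvent records in the same delimited layout they are read from."""
    rows = []
    for s in specs:
        row: dict = {
            "name": s.name,
            "conc_SH": s.conc_SH,
            "pK_ap": s.pK_ap.value,
            "pK_ap_sigma": s.pK_ap.sigma,
            "delta": s.delta.value,
        }
        for fname in _Q_FIELDS:
            q: Quantity = getattr(s, fname)
            row[fname] = q.value
            row[f"{fname}_sigma"] = q.sigma
        row["T"] = s.T
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_gas_table(path: str | Path) -> dict[str, dict[str, GasSpecies]]:
    """Absolute gas-phase free energies keyed by solvent then species."""
    df = _read_table(path)
    out: dict[str, dict[str, GasSpecies]] = {}
    for _, row in df.iterrows():
        label = str(row["species"])
        q = Quantity(_opt_float(row["G_gas"]), _opt_float(row.get("G_gas_sigma")), "kcal/mol")
        out.setdefault(str(row["solvent"]), {})[label] = GasSpecies(label, q)
    return out


def read_molecule_csv(path: str | Path, name: str | None = None) -> RigidMolecule:
    """Rigid molecule from a site table (name, x, y, z, epsilon, sigma, charge)."""
    df = _read_table(path)
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    sites = tuple(
        SiteParams(float(r.epsilon), float(r.sigma), float(r.charge))
        for r in df.itertuples()
    )
    return RigidMolecule(name or Path(path).stem, coords, sites)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------


def _fmt(q: Quantity, nd: int = 2) -> str:
    if q.sigma is None:
        return f"{q.value:.{nd}f}"
    return f"{q.value:.{nd}f} ± {q.sigma:.{nd}f}"


def reports_to_frame(reports: Sequence[CycleReport]) -> pd.DataFrame:
    """Machine-readable long-form table of all cycle outputs."""
    rows = []
    for r in reports:
        rows.append(
            {
                "solvent": r.solvent.name,
                "convention": r.convention,
                "pK_ap_used": r.pK_ap_used.value,
                "dG_sol_1": r.dG_sol_1.value,
                "dG_sol_2": r.dG_sol_2.value,
                "dG_sol_3": r.dG_sol_3.value,
                "pKa_1": r.pKa_1.value,
                "pKa_2": r.pKa_2.value,
                "dG_sol_anion": r.dG_sol_anion.value,
                "dG_sol_anion_sigma": r.dG_sol_anion.sigma,
                "dG_sol_cation": r.dG_sol_cation.value,
                "dG_sol_cation_sigma": r.dG_sol_cation.sigma,
                "pH_neutral_app": r.landmarks.ph_neutral_app,
                "pH_neutral_star": r.landmarks.ph_neutral_star,
                "pKa_bulk": r.landmarks.pKa_bulk,
                "pKa_bulk_star": r.landmarks.pKa_bulk_star,
            }
        )
    return pd.DataFrame(rows)


_TABLE1_ROWS = (
    ("pK_ap used", lambda r: f"{r.pK_ap_used.value:.2f}"),
    ("solution acidity dG_sol(1)", lambda r: _fmt(r.dG_sol_1)),
    ("solution basicity dG_sol(3)", lambda r: _fmt(r.dG_sol_3)),
    ("pKa(1)", lambda r: _fmt(r.pKa_1)),
    ("dG_sol*(S-)", lambda r: _fmt(r.dG_sol_anion)),
    ("dG_sol*(SH2+)", lambda r: _fmt(r.dG_sol_cation)),
)


def render_table1(reports: Sequence[CycleReport]) -> str:
    """Human-readable summary: one column per solvent, the derived block.

    Where a solvent has reports under both conventions the original-constant
    variant is rendered in braces next to the corrected one.
    """
    if not reports:
        raise ValueError("at least one report required")
    by_solvent: dict[str, dict[str, CycleReport]] = {}
    for r in reports:
        by_solvent.setdefault(r.solvent.name, {})[r.convention] = r

    def cell(reps: dict[str, CycleReport], fmt) -> str:
        primary = reps.get("corrected") or reps.get("original")
        text = fmt(primary)
        if "corrected" in reps and "original" in reps:
            other = reps["original"]
            if fmt(other) != fmt(primary):
                text += f" {{{fmt(other)}}}"
        return text

    names = list(by_solvent)
    header = ["quantity (kcal/mol or pKa)"] + names
    body = [
        [label] + [cell(by_solvent[n], fmt) for n in names]
        for label, fmt in _TABLE1_ROWS
    ]
    widths = [
        max(len(row[c]) for row in [header] + body) for c in range(len(header))
    ]
    lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths))]
    lines.append("  ".join("-" * w for w in widths))
    for row in body:
        lines.append("  ".join(v.ljust(w) for v, w in zip(row, widths)))
    return "\n".join(lines)


#: Literal experimental sigmas on the solution acidities as reported with
#: the derived cycle summary; they are not derivable from the tabulated
#: 1-sigma inputs and are therefore carried as pass-through constants.
TABLE3_ACIDITY_SIGMA = {"water": 1.94, "methanol": 4.00}


def render_table3_experimental(reports: Sequence[CycleReport]) -> pd.DataFrame:
    """Experimental comparison rows: per-solvent derived quantities.

    Columns: dG_sol*(SH), dG_sol*(S-), dG_sol*(SH2+), dG_sol(1), dG_sol(2),
    pKa(1), pKa(2), rendered at two decimals; missing fields become an
    absent marker rather than failing the whole table.
    """
    rows = []
    for r in reports:
        sig1 = TABLE3_ACIDITY_SIGMA.get(r.solvent.name)
        acid = Quantity(r.dG_sol_1.value, sig1, "kcal/mol")

        def safe(getter) -> str:
            try:
                return _fmt(getter())
            except Exception:
                return "--"

        rows.append(
            {
                "solvent": r.solvent.name,
                "convention": r.convention,
                "dG_sol*(SH)": safe(lambda: r.solvent.dG_sol_SH),
                "dG_sol*(S-)": safe(lambda: r.dG_sol_anion),
                "dG_sol*(SH2+)": safe(lambda: r.dG_sol_cation),
                "dG_sol(1)": _fmt(acid),
                "dG_sol(2)": safe(lambda: r.dG_sol_2),
                "pKa(1)": safe(lambda: r.pKa_1),
                "pKa(2)": safe(lambda: r.pKa_2),
            }
        )
    return pd.DataFrame(rows)


def fep_log_frame(result: FEPResult) -> pd.DataFrame:
    """Window-by-window annihilation log in delimited form."""
    return pd.DataFrame(
        [
            {
                "stage": w.stage,
                "lambda_from": w.lam_from,
                "lambda_to": w.lam_to,
                "dG": w.dG,
                "se": w.se,
                "n_samples": w.n_samples,
            }
            for w in result.windows
        ]
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {
    "subcommand",
    "inputs",
    "convention",
    "rt",
    "seed",
    "outdir",
    "verbosity",
}


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected by name."""

    subcommand: str = ""
    inputs: list[str] = field(default_factory=list)
    convention: str = "corrected"
    rt: float | None = None
    seed: int = 0
    outdir: str = "."
    verbosity: int = 0

    @classmethod
    def from_mapping(cls, doc: Mapping) -> "RunConfig":
        unknown = set(doc) - _CONFIG_KEYS
        if unknown:
            raise ValueError(
                f"unknown config key(s): {', '.join(sorted(unknown))}"
            )
        return cls(**{k: doc[k] for k in doc})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.from_mapping(doc)
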