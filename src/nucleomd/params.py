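"""Force-field parameters and physical constants.

All numeric force-field coefficients are read from a versioned plain-text
parameter file (see ``data/default_v1.prm``); the energy evaluators receive
them through :class:`ForceFieldParameters` and contain no numeric constants
of their own.

Unit system: energy kcal/mol, length Angstrom, mass g/mol, temperature K.
The intrinsic time unit t0 = sqrt(g/mol * A^2 / (kcal/mol)) ~ 48.89 fs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

# Physical constants in the package unit system
KB = 0.0019872041          # Boltzmann constant, kcal/mol/K
COULOMB_K = 332.0637128    # e^2 * N_A / (4 pi eps0), kcal/mol * A
KCAL_PER_MOL_PER_A_IN_PN = 69.4786     # 1 kcal/mol/A in piconewton
T0_FS = 48.8882            # one internal time unit in femtoseconds


class ParameterFileError(ValueError):
    """Raised when a parameter file is missing, malformed, or incomplete."""


def _parse_prm(text: str) -> dict[str, dict[str, float | str]]:
    sections: dict[str, dict[str, float | str]] = {}
    current: dict[str, float | str] | None = None
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = sections.setdefault(line[1:-1].strip(), {})
            continue
        if "=" not in line:
            raise ParameterFileError(f"line {lineno}: expected 'key = value', got {raw!r}")
        if current is None:
            raise ParameterFileError(f"line {lineno}: entry outside any [section]")
        key, val = (s.strip() for s in line.split("=", 1))
        try:
            current[key] = float(val)
        except ValueError:
            current[key] = val
    return sections


@dataclass
class ForceFieldParameters:
    """Complete coefficient set for V_total = V_pro + V_dna + V_pro-dna.

    Constructed from a parameter file via :meth:`from_file` /
    :meth:`default`. ``salt_mM`` and ``temperature`` are runtime conditions;
    the Debye length is derived from them and recomputed whenever
    :meth:`set_salt` is called.
    """

    # protein
    k_bond_pro: float
    k_angle_pro: float
    k_dih1_pro: float
    k_dih3_pro: float
    eps_go_pro: float
    eps_ev_pro: float
    sigma_ev_pro: float
    ev_cutoff_factor_pro: float
    # dna
    k_bond2_dna: float
    k_bond4_dna: float
    k_angle_dna: float
    k_dih_dna: float
    eps_stack: float
    eps_bp: dict[str, float]
    sigma_bp: dict[str, float]
    eps_ev_dna: float
    sigma_ev_dna: float
    eps_solv: float
    alpha_solv: float
    r_solv: float
    # protein-dna
    go_scaling: float
    eps_ev_prodna: float
    sigma_ev_prodna: float
    ev_cutoff_factor_prodna: float
    # electrostatics / conditions
    dielectric: float
    cutoff_debye_multiple: float
    salt_mM: float = 150.0
    temperature: float = 300.0
    # contact policy
    contact_cutoff: float = 6.5
    min_seq_separation: int = 4
    # geometry + masses
    dna_geometry: dict[str, float] = field(default_factory=dict)
    masses: dict[str, float] = field(default_factory=dict)
    source: str = ""
    version: int = 1

    # ------------------------------------------------------------------
    @classmethod
    def from_file(cls, path: str | Path, salt_mM: float = 150.0,
                  temperature: float = 300.0) -> "ForceFieldParameters":
        path = Path(path)
        if not path.exists():
            raise ParameterFileError(f"parameter file not found: {path}")
        return cls.from_text(path.read_text(), source=str(path),
                             salt_mM=salt_mM, temperature=temperature)

    @classmethod
    def from_text(cls, text: str, source: str = "<text>", salt_mM: float = 150.0,
                  temperature: float = 300.0) -> "ForceFieldParameters":
        sec = _parse_prm(text)

        def need(section: str, key: str) -> float:
            try:
                v = sec[section][key]
            except KeyError:
                raise ParameterFileError(
                    f"missing parameter [{section}] {key} in {source}") from None
            if not isinstance(v, float):
                raise ParameterFileError(f"[{section}] {key}: expected number, got {v!r}")
            return v

        p = cls(
            k_bond_pro=need("protein", "k_bond"),
            k_angle_pro=need("protein", "k_angle"),
            k_dih1_pro=need("protein", "k_dihedral_1"),
            k_dih3_pro=need("protein", "k_dihedral_3"),
            eps_go_pro=need("protein", "eps_go"),
            eps_ev_pro=need("protein", "eps_ev"),
            sigma_ev_pro=need("protein", "sigma_ev"),
            ev_cutoff_factor_pro=need("protein", "ev_cutoff_factor"),
            k_bond2_dna=need("dna", "k_bond_2"),
            k_bond4_dna=need("dna", "k_bond_4"),
            k_angle_dna=need("dna", "k_angle"),
            k_dih_dna=need("dna", "k_dihedral"),
            eps_stack=need("dna", "eps_stack"),
            eps_bp={"AT": need("dna", "eps_bp_AT"), "GC": need("dna", "eps_bp_GC")},
            sigma_bp={"AT": need("dna", "sigma_bp_AT"), "GC": need("dna", "sigma_bp_GC")},
            eps_ev_dna=need("dna", "eps_ev"),
            sigma_ev_dna=need("dna", "sigma_ev"),
            eps_solv=need("dna", "eps_solv"),
            alpha_solv=need("dna", "alpha_solv"),
            r_solv=need("dna", "r_solv"),
            go_scaling=need("pro_dna", "go_scaling"),
            eps_ev_prodna=need("pro_dna", "eps_ev"),
            sigma_ev_prodna=need("pro_dna", "sigma_ev"),
            ev_cutoff_factor_prodna=need("pro_dna", "ev_cutoff_factor"),
            dielectric=need("electrostatics", "dielectric"),
            cutoff_debye_multiple=need("electrostatics", "cutoff_debye_multiple"),
            contact_cutoff=need("contacts", "cutoff"),
            min_seq_separation=int(need("contacts", "min_sequence_separation")),
            dna_geometry={k: float(v) for k, v in sec.get("dna_geometry", {}).items()},
            masses={k: float(v) for k, v in sec.get("masses", {}).items()},
            source=source,
            version=int(need("meta", "schema_version")),
            salt_mM=salt_mM,
            temperature=temperature,
        )
        for name in ("eps_go_pro", "eps_ev_pro", "sigma_ev_pro", "eps_stack",
                     "eps_ev_dna", "sigma_ev_dna", "k_bond_pro", "k_angle_pro"):
            if getattr(p, name) < 0:
                raise ParameterFileError(f"{name} must be non-negative")
        return p

    @classmethod
    def default(cls, salt_mM: float = 150.0,
                temperature: float = 300.0) -> "ForceFieldParameters":
        """Load the packaged default parameter set."""
        text = (resources.files("nucleomd") / "data" / "default_v1.prm").read_text()
        return cls.from_text(text, source="nucleomd:data/default_v1.prm",
                             salt_mM=salt_mM, temperature=temperature)

    # ------------------------------------------------------------------
    @property
    def eps_go_prodna(self) -> float:
        """Protein-DNA contact strength: scaling x protein contact strength."""
        return self.go_scaling * self.eps_go_pro

    @property
    def debye_length(self) -> float:
        """Debye screening length in Angstrom at the current salt and T."""
        return debye_length(self.salt_mM, self.dielectric, self.temperature)

    def set_salt(self, salt_mM: float) -> None:
        if salt_mM <= 0:
            raise ValueError("salt concentration must be positive (mM)")
        self.salt_mM = salt_mM

    def mass_of(self, name: str) -> float:
        try:
            return self.masses[name]
        except KeyError:
            raise ParameterFileError(f"no mass tabulated for bead name {name!r}") from None


def debye_length(salt_mM: float, dielectric: float = 78.0,
                 temperature: float = 300.0) -> float:
    """Debye length (A) of a 1:1 electrolyte.

    lambda_D = sqrt(eps0 eps_r k_B T / (2 N_A e^2 I)), I the ionic strength,
    which for NaCl equals the molar concentration.
    """
    if salt_mM <= 0:
        raise ValueError("salt concentration must be positive (mM)")
    eps0 = 8.8541878128e-12
    kb = 1.380649e-23
    e = 1.602176634e-19
    na = 6.02214076e23
    ionic = salt_mM  # mol/m^3 (1 mM = 1 mol/m^3), 1:1 salt
    lam_m = math.sqrt(eps0 * dielectric * kb * temperature / (2 * na * e * e * ionic))
    return lam_m * 1e10
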