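"""In vivo substrate-specificity quantitation.

Free fatty acids accumulating in the growth medium of an E. coli strain
expressing an acyl-ACP thioesterase are quantified from GC-MS peak areas
against spiked internal standards (heptanoic 7:0, undecanoic 11:0 and
heptadecanoic 17:0 acid), the background produced by a control strain
carrying an empty plasmid is subtracted, and the result is summarized as a
mol% composition vector — the enzyme's substrate-specificity profile.

Analyte identities are fatty acids written as ``carbons:double_bonds``
(e.g. ``"8:0"``, ``"16:1"``) or methylketone names (e.g. ``"2-tridecanone"``);
methylketones are quantified the same way but reported relative to the
fatty-acid total rather than inside it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import QuantitationError

_FA_RE = re.compile(r"^(\d+):(\d+)$")

#: Carbon counts for methylketone trivial names (2-ketones).
_KETONE_CARBONS = {
    "2-butanone": 4, "2-pentanone": 5, "2-hexanone": 6, "2-heptanone": 7,
    "2-octanone": 8, "2-nonanone": 9, "2-decanone": 10, "2-undecanone": 11,
    "2-dodecanone": 12, "2-tridecanone": 13, "2-tetradecanone": 14,
    "2-pentadecanone": 15, "2-hexadecanone": 16, "2-heptadecanone": 17,
}


def is_fatty_acid(species: str) -> bool:
    return bool(_FA_RE.match(species.strip()))


def carbon_number(species: str) -> int:
    """Carbon count of an analyte (fatty acid or methylketone)."""
    s = species.strip()
    m = _FA_RE.match(s)
    if m:
        return int(m.group(1))
    if s.lower() in _KETONE_CARBONS:
        return _KETONE_CARBONS[s.lower()]
    raise QuantitationError(f"unparseable analyte species {species!r}")


@dataclass(frozen=True)
class AnalytePeak:
    species: str
    area: float

    def __post_init__(self) -> None:
        if self.area < 0:
            raise QuantitationError(
                f"negative peak area for {self.species!r}"
            )
        carbon_number(self.species)  # validates


@dataclass(frozen=True)
class InternalStandard:
    species: str
    mass_ug: float
    molecular_weight: float  # g/mol

    def nmol_per_ml(self, volume_ml: float) -> float:
        # ug / (g/mol) = umol; 1000x to nmol; divided by sample volume
        return self.mass_ug / self.molecular_weight * 1000.0 / volume_ml


@dataclass
class InternalStandardSet:
    """The spiked standards and the chain-length -> standard mapping.

    Defaults reproduce the assay recipe: 10 ug 7:0 + 10 ug 11:0 + 20 ug
    17:0 in a 2 mL medium sample.  Analytes are assigned to a standard by
    carbon number: <= 9 carbons -> 7:0, 10-12 -> 11:0, >= 13 -> 17:0
    (C9, unassigned by the stated C4-C8 / C10-C12 ranges, goes to 7:0).
    """

    standards: dict[str, InternalStandard] = field(default_factory=lambda: {
        "7:0": InternalStandard("7:0", 10.0, 130.18),
        "11:0": InternalStandard("11:0", 10.0, 186.29),
        "17:0": InternalStandard("17:0", 20.0, 270.45),
    })
    volume_ml: float = 2.0

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise QuantitationError("sample volume must be positive")
        for std in self.standards.values():
            if std.mass_ug <= 0 or std.molecular_weight <= 0:
                raise QuantitationError(
                    f"standard {std.species!r} must have positive mass and MW"
                )

    def assign(self, species: str) -> str:
        c = carbon_number(species)
        if c <= 9:
            return "7:0"
        if c <= 12:
            return "11:0"
        return "17:0"

    def concentration(self, std_species: str) -> float:
        return self.standards[std_species].nmol_per_ml(self.volume_ml)


@dataclass
class SpecificityProfile:
    """Net product concentrations and mol% composition for one enzyme."""

    enzyme_id: str
    net_concentration: dict[str, float]  # species -> nmol/mL
    mol_percent: dict[str, float]        # fatty acids only, sums to 100
    total_fa: float                      # nmol/mL
    methylketone_molpct: dict[str, float] = field(default_factory=dict)


def quantify(
    peaks: list[AnalytePeak],
    standards: InternalStandardSet | None = None,
    response_factors: dict[str, float] | None = None,
) -> dict[str, float]:
    """Convert peak areas to concentrations (nmol/mL) via internal standards.

    concentration = (area_analyte / area_IS) * response_factor * [IS],
    with the IS chosen by the analyte's carbon number.  Molar response
    factors default to 1.0 for every analyte.  Raises
    :class:`QuantitationError` when a required standard peak is missing or
    has zero area.
    """
    standards = standards or InternalStandardSet()
    rf = response_factors or {}
    areas = {}
    for p in peaks:
        if p.species in areas:
            raise QuantitationError(f"duplicate peak for {p.species!r}")
        areas[p.species] = p.area
    for std in standards.standards:
        if std not in areas:
            raise QuantitationError(f"missing internal standard peak {std!r}")
        if areas[std] == 0:
            raise QuantitationError(f"zero-area internal standard {std!r}")
    out = {}
    for p in peaks:
        if p.species in standards.standards:
            continue
        std = standards.assign(p.species)
        conc = (
            p.area / areas[std]
            * rf.get(p.species, 1.0)
            * standards.concentration(std)
        )
        out[p.species] = conc
    return out


def background_subtract(
    sample: dict[str, float],
    control: dict[str, float],
    clamp_log: list[str] | None = None,
) -> dict[str, float]:
    """Net production = max(sample - control, 0) per species.

    The control map holds concentrations produced by the empty-plasmid
    strain; species absent from either map count as zero.  Species clamped
    at zero are appended to ``clamp_log`` when provided.
    """
    species = set(sample) | set(control)
    net = {}
    for s in sorted(species, key=lambda x: (carbon_number(x), x)):
        value = sample.get(s, 0.0) - control.get(s, 0.0)
        if value < 0:
            if clamp_log is not None:
                clamp_log.append(
                    f"{s}: net {value:.4g} nmol/mL clamped to 0"
                )
            value = 0.0
        net[s] = value
    return net


def compose_profile(net: dict[str, float], enzyme_id: str) -> SpecificityProfile:
    """Mol% composition from net concentrations.

    The denominator is the fatty-acid total only; methylketones are
    expressed as mol% of that same fatty-acid total, so the fatty-acid
    mol%s alone sum to 100.  Raises when nothing is above background.
    """
    fa = {s: v for s, v in net.items() if is_fatty_acid(s)}
    mk = {s: v for s, v in net.items() if not is_fatty_acid(s)}
    total = sum(fa.values())
    if total <= 0:
        raise QuantitationError(
            f"no activity above background for {enzyme_id!r}"
        )
    mol_percent = {s: 100.0 * v / total for s, v in fa.items()}
    mk_pct = {s: 100.0 * v / total for s, v in mk.items() if v > 0}
    return SpecificityProfile(enzyme_id, dict(net), mol_percent, total, mk_pct)


# ---------------------------------------------------------------------------
# Table-level interface
# ---------------------------------------------------------------------------

def read_peak_table(path) -> dict[str, list[AnalytePeak]]:
    """Read a CSV of (enzyme, species, area) into per-enzyme peak lists."""
    df = pd.read_csv(path)
    required = {"enzyme", "species", "area"}
    if not required <= set(df.columns):
        raise QuantitationError(
            f"peak table must have columns {sorted(required)}"
        )
    if df.empty:
        raise QuantitationError(f"peak table {path} contains no rows")
    out: dict[str, list[AnalytePeak]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.enzyme), []).append(
            AnalytePeak(str(row.species), float(row.area))
        )
    return out


def read_concentration_table(path) -> dict[str, dict[str, float]]:
    """Read a CSV of (enzyme, species, nmol_per_mL) concentration maps."""
    df = pd.read_csv(path)
    required = {"enzyme", "species", "nmol_per_mL"}
    if not required <= set(df.columns):
        raise QuantitationError(
            f"concentration table must have columns {sorted(required)}"
        )
    out: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.enzyme), {})[str(row.species)] = float(
            row.nmol_per_mL
        )
    return out


def profiles_from_peak_tables(
    peak_tables: dict[str, list[AnalytePeak]],
    control_peaks: list[AnalytePeak] | dict[str, float] | None,
    standards: InternalStandardSet | None = None,
    response_factors: dict[str, float] | None = None,
    clamp_log: list[str] | None = None,
) -> list[SpecificityProfile]:
    """Full pipeline: quantify -> background subtract -> compose, per enzyme."""
    standards = standards or InternalStandardSet()
    if control_peaks is None:
        control = {}
    elif isinstance(control_peaks, dict):
        control = control_peaks
    else:
        control = quantify(control_peaks, standards, response_factors)
    profiles = []
    for enzyme_id in sorted(peak_tables):
        conc = quantify(peak_tables[enzyme_id], standards, response_factors)
        net = background_subtract(conc, control, clamp_log)
        profiles.append(compose_profile(net, enzyme_id))
    return profiles


def profiles_to_frame(profiles: list[SpecificityProfile]) -> pd.DataFrame:
    """Long-format table (enzyme, species, net_nmol_per_mL, mol_pct)."""
    rows = []
    for p in profiles:
        for s, v in sorted(
            p.net_concentration.items(), key=lambda kv: (carbon_number(kv[0]), kv[0])
        ):
            rows.append(
                {
                    "enzyme": p.enzyme_id,
                    "species": s,
                    "net_nmol_per_mL": v,
                    "mol_pct": p.mol_percent.get(
                        s, p.methylketone_molpct.get(s, 0.0)
                    ),
                    "is_fatty_acid": is_fatty_acid(s),
                    "total_fa_nmol_per_mL": p.total_fa,
                }
            )
    return pd.DataFrame(rows)


def molpct_matrix(profiles: list[SpecificityProfile]) -> pd.DataFrame:
    """Wide mol% matrix (enzymes x fatty-acid species), zeros for absences."""
    species = sorted(
        {s for p in profiles for s in p.mol_percent},
        key=lambda x: (carbon_number(x), x),
    )
    data = {
        p.enzyme_id: [p.mol_percent.get(s, 0.0) for s in species]
        for p in profiles
    }
    return pd.DataFrame(data, index=species).T
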