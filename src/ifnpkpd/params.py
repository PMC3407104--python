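"""Parameter containers for the hepatic gene-expression PK/PD model.

The model describes a plasmid dose delivered to the mouse liver by
hydrodynamic injection: nuclear DNA (two activity states) is transcribed
into mRNA, mRNA drives hepatic protein synthesis through a chain of transit
compartments, the protein exchanges between liver and serum (with an
optional peripheral distribution space for the ApoAI fusion), enters the
brain by a slow first-order process, and induces interferon-stimulated
genes (ISGs) in liver and brain through turnover models.

All rate constants are first order with units 1/h unless noted otherwise.
Liver and brain protein density is taken as 1 mg/mL and the distribution
volume as 1 mL, so amounts (pg) and concentrations (pg/mL, pg/mg protein)
are numerically interchangeable throughout.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = [
    "TranscriptionParams",
    "PeripheralExchange",
    "HepaticProteinParams",
    "BrainParams",
    "ISGParams",
    "KineticParameterSet",
    "load_parameter_set",
    "save_parameter_set",
]


def _check_positive(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
        raise ValueError(f"{name} must be a strictly positive finite number, got {value!r}")


def _check_nonnegative(name: str, value: float) -> None:
    if not (isinstance(value, (int, float)) and math.isfinite(value) and value >= 0):
        raise ValueError(f"{name} must be a nonnegative finite number, got {value!r}")


@dataclass(frozen=True)
class TranscriptionParams:
    """Nuclear DNA -> mRNA kinetics.

    Two coexisting activity states of the delivered plasmid (DNA and DNA')
    both drive mRNA synthesis, with different efficiencies.

    Parameters
    ----------
    k_nunc : 1/h
        First-order degradation rate of the primary DNA pool.
    k_int : 1/h
        Single rate constant governing both formation and elimination of
        the secondary pool DNA'.
    k_s1, k_s2 : gene-expression-units / h per DNA unit
        mRNA synthesis rates from DNA and DNA' respectively.
    k_deg : 1/h
        First-order mRNA degradation rate.
    conversion_depletes_dna :
        If True (default) the DNA -> DNA' conversion removes material from
        the DNA pool (dDNA/dt = -(k_nunc + k_int)·DNA); if False the
        conversion is non-depleting (dDNA/dt = -k_nunc·DNA).
    """

    k_nunc: float
    k_int: float
    k_s1: float
    k_s2: float
    k_deg: float
    conversion_depletes_dna: bool = True

    def __post_init__(self) -> None:
        for name in ("k_nunc", "k_int", "k_s1", "k_s2", "k_deg"):
            _check_positive(name, getattr(self, name))


@dataclass(frozen=True)
class PeripheralExchange:
    """Serum <-> peripheral distribution rates (1/h)."""

    k_sp: float
    k_ps: float

    def __post_init__(self) -> None:
        _check_positive("k_sp", self.k_sp)
        _check_positive("k_ps", self.k_ps)


@dataclass(frozen=True)
class HepaticProteinParams:
    """mRNA -> hepatic protein -> serum kinetics.

    Parameters
    ----------
    k_s : pg/h per gene-expression-unit
        Hepatic protein synthesis rate, driven by the last transit
        compartment (or directly by mRNA when ``n_transit == 0``).
    k_d : 1/h
        Hepatic protein degradation rate.
    k_tran : 1/h
        Transit rate through the synthesis-delay chain.
    n_transit :
        Number of transit compartments (0 disables the delay).
    k_ls, k_sl : 1/h
        Liver -> serum and serum -> liver exchange rates.
    k_sb : 1/h
        Serum -> brain input rate.
    peripheral :
        Optional serum <-> peripheral exchange block (present for the
        ApoAI-fusion model variant, absent for the plain fusion).
    """

    k_s: float
    k_d: float
    k_tran: float
    k_ls: float
    k_sl: float
    k_sb: float
    n_transit: int = 3
    peripheral: PeripheralExchange | None = None

    def __post_init__(self) -> None:
        for name in ("k_s", "k_d", "k_tran", "k_ls", "k_sl", "k_sb"):
            _check_positive(name, getattr(self, name))
        if not (isinstance(self.n_transit, int) and self.n_transit >= 0):
            raise ValueError(f"n_transit must be a nonnegative integer, got {self.n_transit!r}")

    @property
    def has_peripheral(self) -> bool:
        return self.peripheral is not None


@dataclass(frozen=True)
class BrainParams:
    """Brain protein disposition: first-order exit/degradation rate k_e (1/h)."""

    k_e: float

    def __post_init__(self) -> None:
        _check_positive("k_e", self.k_e)


@dataclass(frozen=True)
class ISGParams:
    """Turnover (indirect-response) model of one interferon-stimulated gene.

    dISG/dt = synthesis(driver) - k_d_isg·ISG, where the driver is the
    model-predicted protein level in the matching organ.  With ``ifn50``
    set, synthesis is saturable, k_s_isg·driver/(driver + ifn50); without
    it, synthesis is linear, k_s_isg·driver.

    Units: k_s_isg is gene-expression-units/h (saturable mode) or
    gene-expression-units·mL/(pg·h) (linear mode); ifn50 is pg/mL; isg0 is
    the initial ISG level in gene-expression units.
    """

    k_s_isg: float
    k_d_isg: float
    ifn50: float | None = None
    isg0: float = 0.0

    def __post_init__(self) -> None:
        _check_positive("k_s_isg", self.k_s_isg)
        _check_positive("k_d_isg", self.k_d_isg)
        if self.ifn50 is not None:
            _check_positive("ifn50", self.ifn50)
        _check_nonnegative("isg0", self.isg0)

    @property
    def is_saturable(self) -> bool:
        return self.ifn50 is not None

    def synthesis(self, driver):
        """Synthesis rate as a function of the (nonnegative) driver level."""
        if self.is_saturable:
            return self.k_s_isg * driver / (driver + self.ifn50)
        return self.k_s_isg * driver


@dataclass(frozen=True)
class KineticParameterSet:
    """All rate constants of the kinetic model for one molecule."""

    molecule: str
    transcription: TranscriptionParams
    protein: HepaticProteinParams
    brain: BrainParams

    def flat(self) -> dict[str, float]:
        """Flat name -> value map of every rate constant."""
        out = {
            name: getattr(self.transcription, name)
            for name in ("k_nunc", "k_int", "k_s1", "k_s2", "k_deg")
        }
        for name in ("k_s", "k_d", "k_tran", "k_ls", "k_sl", "k_sb"):
            out[name] = getattr(self.protein, name)
        if self.protein.peripheral is not None:
            out["k_sp"] = self.protein.peripheral.k_sp
            out["k_ps"] = self.protein.peripheral.k_ps
        out["k_e"] = self.brain.k_e
        return out


# units registry used by the serializers (annotation only, never parsed back)
_UNITS = {
    "k_nunc": "1/h", "k_int": "1/h", "k_deg": "1/h",
    "k_s1": "gene-expression-units/h per DNA-unit",
    "k_s2": "gene-expression-units/h per DNA-unit",
    "k_s": "pg/h per gene-expression-unit",
    "k_d": "1/h", "k_tran": "1/h", "k_ls": "1/h", "k_sl": "1/h",
    "k_sb": "1/h", "k_sp": "1/h", "k_ps": "1/h", "k_e": "1/h",
    "n_transit": "count",
}


def parameter_set_to_dict(params: KineticParameterSet) -> dict[str, Any]:
    d = dataclasses.asdict(params)
    d["units"] = dict(_UNITS)
    return d


def parameter_set_from_dict(d: dict[str, Any]) -> KineticParameterSet:
    d = dict(d)
    d.pop("units", None)
    tr = TranscriptionParams(**d["transcription"])
    prot = dict(d["protein"])
    per = prot.pop("peripheral", None)
    protein = HepaticProteinParams(
        **prot, peripheral=PeripheralExchange(**per) if per else None
    )
    brain = BrainParams(**d["brain"])
    return KineticParameterSet(
        molecule=d["molecule"], transcription=tr, protein=protein, brain=brain
    )


def save_parameter_set(params: KineticParameterSet, path) -> None:
    """Write a parameter set to YAML (``.yaml``/``.yml``) or JSON."""
    d = parameter_set_to_dict(params)
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(d, fh, indent=2)
        else:
            yaml.safe_dump(d, fh, sort_keys=False)


def load_parameter_set(path) -> KineticParameterSet:
    path = str(path)
    with open(path) as fh:
        d = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    return parameter_set_from_dict(d)
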