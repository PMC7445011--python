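"""Simulation configuration.

A single :class:`SimConfig` drives every generator in :mod:`utrclip.simulate`.
All generators are pure functions of the configuration (including its seed),
so an identical config yields a byte-identical fixture bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised when a SimConfig field is out of range; names the field."""


def _default_barcodes() -> dict[str, str]:
    # three signal iCLIP replicates plus an IgG-style background control
    return {"rep1": "ACCT", "rep2": "GGTA", "rep3": "TCGA", "IgG": "CATG"}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe the fixture exercised end to end in the tests: a
    ~200-gene toy genome, three iCLIP replicates plus an IgG control with
    motif-driven crosslink placement, a germ-cell expression table and a
    12-tissue atlas, RiboTag count matrices with a planted log2 translational
    effect on targets, and conservation tracks elevated at planted sites.
    """

    seed: int = 0
    n_genes: int = 200

    # gene architecture (nt)
    utr5_length_range: tuple[int, int] = (80, 200)
    cds_codon_range: tuple[int, int] = (100, 300)
    utr3_length_range: tuple[int, int] = (250, 800)
    intron_length_range: tuple[int, int] = (80, 300)
    max_introns: int = 2
    intergenic_gap_range: tuple[int, int] = (100, 300)
    ncrna_fraction: float = 0.04
    retrogene_fraction: float = 0.02

    # base composition of background sequence, order A C G U
    motif_alphabet_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    # planted binding program
    target_fraction: float = 0.2
    sites_per_target: tuple[int, int] = (2, 6)  # inclusive uniform range
    planted_motif: str = "UGUU(U/A)"
    # fractions of planted sites in an end-proximal window, a start-proximal
    # window, and uniform over the 3' UTR (sums to 1)
    site_position_bias: tuple[float, float, float] = (0.5, 0.3, 0.2)
    end_window: tuple[int, int] = (20, 100)  # nt from 3' UTR end
    start_window: tuple[int, int] = (100, 240)  # nt from 3' UTR start

    # iCLIP library
    crosslink_signal_rate: float = 400.0  # expected reads per site per million
    background_rate: float = 1.0  # expected reads per nt per million, avg-TPM gene
    pcr_duplication_rate: float = 0.2
    n_replicates: int = 3
    barcode_map: dict[str, str] = field(default_factory=_default_barcodes)
    library_sizes: int = 100_000  # reads per iCLIP sample
    read_length: int = 35  # insert length after barcode removal

    # RiboTag
    te_effect: float = 0.4  # planted log2 TE shift on targets (delta)
    nb_dispersion: float = 0.01  # var = mu + alpha mu^2
    ribotag_depth: float = 2e6  # expected reads per RiboTag sample
    n_ribotag_replicates: int = 3

    # expression atlas
    n_tissues: int = 12
    testis_specific_fraction: float = 0.08

    # conservation tracks; applied to both tracks, in phyloP-like score units
    conservation_boost: float = 2.0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        probs = {
            "target_fraction": self.target_fraction,
            "pcr_duplication_rate": self.pcr_duplication_rate,
            "ncrna_fraction": self.ncrna_fraction,
            "retrogene_fraction": self.retrogene_fraction,
            "testis_specific_fraction": self.testis_specific_fraction,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        counts = {
            "n_genes": self.n_genes,
            "n_replicates": self.n_replicates,
            "n_tissues": self.n_tissues,
            "library_sizes": self.library_sizes,
            "read_length": self.read_length,
            "max_introns": self.max_introns,
            "n_ribotag_replicates": self.n_ribotag_replicates,
        }
        for name, c in counts.items():
            if c < 0 or int(c) != c:
                raise ConfigError(f"{name} must be a non-negative integer, got {c}")
        if self.n_genes < 1:
            raise ConfigError(f"n_genes must be >= 1, got {self.n_genes}")
        freqs = np.asarray(self.motif_alphabet_freqs, dtype=float)
        if freqs.shape != (4,) or (freqs < 0).any() or abs(freqs.sum() - 1.0) > 1e-9:
            raise ConfigError(
                "motif_alphabet_freqs must be 4 probabilities over A,C,G,U summing to 1"
            )
        for name in (
            "utr5_length_range",
            "cds_codon_range",
            "utr3_length_range",
            "intron_length_range",
            "intergenic_gap_range",
            "sites_per_target",
        ):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigError(f"{name} must be a positive (lo, hi) range, got {(lo, hi)}")
        if self.nb_dispersion < 0:
            raise ConfigError(f"nb_dispersion must be >= 0, got {self.nb_dispersion}")
        for rate in ("crosslink_signal_rate", "background_rate", "ribotag_depth"):
            if getattr(self, rate) < 0:
                raise ConfigError(f"{rate} must be >= 0")
        codes = list(self.barcode_map.values())
        if len(set(codes)) != len(codes):
            raise ConfigError("barcode_map sample codes must be pairwise distinct")
        for sample, code in self.barcode_map.items():
            if len(code) != 4 or set(code) - set("ACGT"):
                raise ConfigError(
                    f"barcode_map[{sample!r}] must be a 4-nt ACGT code, got {code!r}"
                )
        bias = np.asarray(self.site_position_bias, dtype=float)
        if (bias < 0).any() or abs(bias.sum() - 1.0) > 1e-9:
            raise ConfigError("site_position_bias must be 3 non-negative weights summing to 1")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in d:
                v = d[f.name]
                if isinstance(v, list):
                    v = tuple(v)
                kwargs[f.name] = v
        return cls(**kwargs)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "SimConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))
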