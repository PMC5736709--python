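"""Simulate multi-domain proteomes with planted CBM40/GH33 architecture."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..alphabet import AA, BACKGROUND
from ..phylo.ratemodel import RateModel, default_model
from .families import _evolve, _to_str

_FIRMICUTES_GENERA = [
    "Ruminococcus", "Clostridium", "Streptococcus", "Lactobacillus",
    "Blautia", "Enterococcus", "Roseburia", "Faecalibacterium",
]
_GAMMA_GENERA = ["Vibrio", "Aeromonas", "Shewanella", "Photobacterium", "Actinobacillus"]


@dataclass
class ProteomeConfig:
    n_proteins: int = 50
    cbm40_rate: float = 0.6
    cooccurrence_rate: float = 0.92
    decoy_rate: float = 0.2
    canonical_fraction: float = 0.5
    linker_length: tuple[int, int] = (30, 80)
    domain_divergence: float = 0.10   # substitutions/site from a family member
    taxon_palette: dict[str, list[tuple[str, str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rate in (self.cbm40_rate, self.cooccurrence_rate, self.decoy_rate,
                     self.canonical_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if not self.taxon_palette:
            self.taxon_palette = {
                "canonical": [("Firmicutes", "Clostridia", g) for g in _FIRMICUTES_GENERA],
                "vibrio": [("Proteobacteria", "Gammaproteobacteria", g) for g in _GAMMA_GENERA],
                "none": [("Bacteroidetes", "Bacteroidia", "Bacteroides")],
            }


@dataclass
class PlantedDomain:
    kind: str            # canonical | vibrio | gh33 | decoy
    start: int
    end: int


@dataclass
class ProteomeSim:
    proteins: list[tuple[str, str]]
    taxonomy: dict[str, tuple[str, str, str]]
    truth: dict[str, dict]   # protein id -> {"domains": [...], "has_gh33": bool, ...}


def _sample_domain(
    family: list[tuple[str, str]], model: RateModel, t: float, rng: np.random.Generator
) -> str:
    _, row = family[rng.integers(0, len(family))]
    idx = np.array([AA.index(c) for c in row if c not in "-."])
    return _to_str(_evolve(idx, model, t, rng))


def _linker(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(AA[i] for i in rng.choice(20, size=n, p=BACKGROUND))


def gen_proteome(
    families: dict[str, list[tuple[str, str]]],
    config: ProteomeConfig | None = None,
    model: RateModel | None = None,
    seed: int = 0,
) -> ProteomeSim:
    """Proteins assembled as linker / planted domains / linker.

    ``families`` maps domain kinds (``canonical``, ``vibrio``, optional
    ``gh33``, ``decoy``) to aligned seed families; planted instances are
    family members evolved by ``domain_divergence`` substitutions/site.
    CBM40-bearing proteins carry a GH33 domain with probability
    ``cooccurrence_rate``; proteins without CBM40 may carry a decoy
    domain.  The truth table records every planted interval.
    """
    config = config or ProteomeConfig()
    model = model or default_model()
    rng = np.random.default_rng(seed)
    lo, hi = config.linker_length

    proteins: list[tuple[str, str]] = []
    taxonomy: dict[str, tuple[str, str, str]] = {}
    truth: dict[str, dict] = {}
    for i in range(config.n_proteins):
        pid = f"prot_{i:04d}"
        has_cbm = rng.random() < config.cbm40_rate
        segments: list[str] = [_linker(rng, lo, hi)]
        domains: list[PlantedDomain] = []
        kind = "none"
        has_gh33 = False

        def plant(k: str) -> None:
            dom = _sample_domain(families[k], model, config.domain_divergence, rng)
            start = sum(len(s) for s in segments)
            segments.append(dom)
            domains.append(PlantedDomain(k, start, start + len(dom)))
            segments.append(_linker(rng, lo, hi))

        if has_cbm:
            kind = (
                "canonical"
                if rng.random() < config.canonical_fraction
                else "vibrio"
            )
            plant(kind)
            if "gh33" in families and rng.random() < config.cooccurrence_rate:
                plant("gh33")
                has_gh33 = True
        elif "decoy" in families and rng.random() < config.decoy_rate:
            plant("decoy")

        seq = "".join(segments)
        palette = config.taxon_palette.get(kind) or config.taxon_palette["none"]
        taxon = palette[int(rng.integers(0, len(palette)))]
        proteins.append((pid, seq))
        taxonomy[pid] = taxon
        truth[pid] = {
            "kind": kind,
            "has_gh33": has_gh33,
            "domains": [(d.kind, d.start, d.end) for d in domains],
            "taxon": taxon,
        }
    return ProteomeSim(proteins=proteins, taxonomy=taxonomy, truth=truth)
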