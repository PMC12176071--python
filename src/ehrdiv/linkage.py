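"""Cross-dataset patient linkage via platform identifiers.

Both processed datasets are uploaded to a trusted data platform which assigns
every person one platform identifier.  SSN-derived pseudonyms resolve
deterministically; pseudonyms derived from (postal-code prefix, birth year,
sex) resolve only when the triple is unique in the registry — ambiguous
triples are unlinkable and their patients drop out of the concordant group.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .containers import ProcessedDataset, RawEhrExtract
from .etl import pseudonymize_frame


@dataclass(frozen=True)
class PlatformRegistry:
    """Maps pseudonyms of either scheme to platform person identifiers."""

    by_ssn: dict[str, str]
    by_pc3: dict[str, str | None]  # None = ambiguous triple, unlinkable


def build_registry(extract: RawEhrExtract) -> PlatformRegistry:
    """Ground-truth registry for a simulated population.

    The simulation plays the role of the national registry: the platform
    identifier is the generator's person key.  pc3 triples shared by more
    than one person map to ``None``.
    """
    pats = extract.patients
    ssn_pseudo = pseudonymize_frame(pats, "ssn")
    by_ssn = {
        p: tid for p, tid in zip(ssn_pseudo, pats["true_id"]) if p is not None
    }
    pc3_pseudo = pseudonymize_frame(pats, "pc3_birthyear_sex")
    groups: dict[str, list[str]] = {}
    for p, tid in zip(pc3_pseudo, pats["true_id"]):
        groups.setdefault(p, []).append(tid)
    by_pc3 = {p: (tids[0] if len(tids) == 1 else None) for p, tids in groups.items()}
    return PlatformRegistry(by_ssn=by_ssn, by_pc3=by_pc3)


def platform_identifier(pseudo_id: str, scheme: str, registry: PlatformRegistry) -> str | None:
    """Resolve a pseudonym to a platform identifier, or ``None`` if unlinkable."""
    if scheme == "ssn":
        return registry.by_ssn.get(pseudo_id)
    if scheme == "pc3_birthyear_sex":
        return registry.by_pc3.get(pseudo_id)
    raise ValueError(f"unknown pseudonym scheme {scheme!r}")


def attach_platform_ids(
    ds: ProcessedDataset, scheme: str, registry: PlatformRegistry
) -> ProcessedDataset:
    """Return *ds* with the patients' ``platform_id`` column filled in."""
    pats = ds.patients.copy()
    pats["platform_id"] = [
        platform_identifier(p, scheme, registry) or "" for p in pats["pseudo_id"]
    ]
    return ProcessedDataset(
        name=ds.name,
        analysis_year=ds.analysis_year,
        patients=pats,
        contacts=ds.contacts,
        claims=ds.claims,
        prescriptions=ds.prescriptions,
        episodes=ds.episodes,
    )


@dataclass(frozen=True)
class ConcordantLink:
    """Population flow between two processed datasets."""

    shared_ids: frozenset[str] = field(repr=False)
    n_a: int
    n_b: int
    n_shared: int
    n_union: int
    n_a_only: int
    n_b_only: int
    concordant_fraction: float

    @classmethod
    def from_id_sets(cls, ids_a: set[str], ids_b: set[str]) -> "ConcordantLink":
        shared = frozenset(ids_a & ids_b)
        union = len(ids_a | ids_b)
        return cls(
            shared_ids=shared,
            n_a=len(ids_a),
            n_b=len(ids_b),
            n_shared=len(shared),
            n_union=union,
            n_a_only=len(ids_a) - len(shared),
            n_b_only=len(ids_b) - len(shared),
            concordant_fraction=(len(shared) / union) if union else 0.0,
        )

    @classmethod
    def from_counts(cls, n_a: int, n_b: int, n_shared: int) -> "ConcordantLink":
        """Population-flow arithmetic from headline counts (no id sets)."""
        union = n_a + n_b - n_shared
        return cls(
            shared_ids=frozenset(),
            n_a=n_a,
            n_b=n_b,
            n_shared=n_shared,
            n_union=union,
            n_a_only=n_a - n_shared,
            n_b_only=n_b - n_shared,
            concordant_fraction=(n_shared / union) if union else 0.0,
        )

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_shared": self.n_shared,
            "n_union": self.n_union,
            "n_a_only": self.n_a_only,
            "n_b_only": self.n_b_only,
            "concordant_fraction": self.concordant_fraction,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def concordant(ds_a: ProcessedDataset, ds_b: ProcessedDataset) -> ConcordantLink:
    """Identify patients present in both datasets by platform identifier.

    Symmetric: swapping the arguments swaps the a/b counts but reports the
    identical shared set.
    """
    ids_a = set(ds_a.patients.loc[ds_a.patients["platform_id"] != "", "platform_id"])
    ids_b = set(ds_b.patients.loc[ds_b.patients["platform_id"] != "", "platform_id"])
    return ConcordantLink.from_id_sets(ids_a, ids_b)


def restrict_to_concordant(ds: ProcessedDataset, link: ConcordantLink) -> ProcessedDataset:
    """Restrict a dataset (all tables) to patients in the concordant group."""
    pats = ds.patients[ds.patients["platform_id"].isin(link.shared_ids)].reset_index(drop=True)
    keep = set(pats["pseudo_id"])

    def _f(df: pd.DataFrame) -> pd.DataFrame:
        return df[df["pseudo_id"].isin(keep)].reset_index(drop=True)

    return ProcessedDataset(
        name=ds.name,
        analysis_year=ds.analysis_year,
        patients=pats,
        contacts=_f(ds.contacts),
        claims=_f(ds.claims),
        prescriptions=_f(ds.prescriptions),
        episodes=_f(ds.episodes),
    )
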