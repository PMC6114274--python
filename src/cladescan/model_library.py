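"""The multi-source domain model library.

Each domain is represented by at most one sequence consensus model (SCM)
and any number of clade-centered models (CCMs), each carrying a consensus
sequence and, for CCMs, the taxon label of the clade the model was built
from.  A library is described on disk by a TSV manifest and an optional
two-column clan table (domain accession TAB clan accession, extra columns
ignored — the Pfam-A.clans dialect).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional


class LibraryError(ValueError):
    pass


@dataclass
class DomainModel:
    """One probabilistic model (SCM or CCM) of a domain.

    ``profile_ref`` is an opaque handle for the search backend: either an
    in-memory PSSM or a path to a serialized profile.
    """

    model_id: str
    domain_acc: str
    model_type: str  # "SCM" | "CCM"
    clade: str = ""
    consensus: str = ""
    profile_ref: object = None

    def __post_init__(self) -> None:
        if self.model_type not in ("SCM", "CCM"):
            raise LibraryError(f"unknown model_type {self.model_type!r} for {self.model_id}")
        if not self.consensus:
            raise LibraryError(f"model {self.model_id} has an empty consensus")


@dataclass
class ModelLibrary:
    models: dict[str, DomainModel] = field(default_factory=dict)  # by model_id
    clan_map: dict[str, str] = field(default_factory=dict)

    def add(self, model: DomainModel) -> None:
        if model.model_id in self.models:
            raise LibraryError(f"duplicate model_id {model.model_id!r}")
        self.models[model.model_id] = model

    def validate(self) -> None:
        scm_domains = {m.domain_acc for m in self.models.values() if m.model_type == "SCM"}
        by_domain_scm: dict[str, int] = {}
        for m in self.models.values():
            if m.model_type == "SCM":
                by_domain_scm[m.domain_acc] = by_domain_scm.get(m.domain_acc, 0) + 1
            elif m.domain_acc not in scm_domains and not any(
                x.domain_acc == m.domain_acc for x in self.models.values()
            ):
                raise LibraryError(f"CCM {m.model_id} has no domain entry {m.domain_acc}")
        for acc, n in by_domain_scm.items():
            if n > 1:
                raise LibraryError(f"domain {acc} has {n} SCMs; at most one allowed")

    @property
    def domain_accs(self) -> list[str]:
        return sorted({m.domain_acc for m in self.models.values()})

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        # stable ordering by model_id for reproducible tie-breaks downstream
        return iter(sorted(self.models.values(), key=lambda m: m.model_id))

    def models_for_domain(self, domain_acc: str) -> tuple[Optional[DomainModel], list[DomainModel]]:
        return models_for_domain(self, domain_acc)

    def clan_of(self, domain_acc: str) -> Optional[str]:
        return self.clan_map.get(domain_acc)


MANIFEST_COLUMNS = ["model_id", "domain_acc", "model_type", "clade", "consensus_or_path"]


def load_library(manifest: str | Path, clans: str | Path | None = None) -> ModelLibrary:
    """Load a model library from its TSV manifest.

    The ``consensus_or_path`` column holds the model consensus directly
    (all-letter token) or a path to a serialized profile whose consensus is
    read from the profile file.  Duplicate model ids and CCMs whose domain
    has no library entry are rejected.
    """
    lib = ModelLibrary()
    with open(manifest, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[: len(MANIFEST_COLUMNS)] != MANIFEST_COLUMNS:
            raise LibraryError(f"unexpected manifest header in {manifest}: {header}")
        for row in reader:
            if not row or row[0].startswith("#"):
                continue
            model_id, domain_acc, model_type, clade, cons = row[:5]
            profile_ref = None
            if "/" in cons or cons.endswith(".tsv"):
                from cladescan.search_backend import load_pssm

                profile_ref = load_pssm(Path(manifest).parent / cons)
                cons = profile_ref.consensus
            lib.add(
                DomainModel(
                    model_id=model_id,
                    domain_acc=domain_acc,
                    model_type=model_type,
                    clade=clade,
                    consensus=cons,
                    profile_ref=profile_ref,
                )
            )
    lib.validate()
    if clans is not None:
        lib.clan_map = load_clan_map(clans)
    return lib


def save_library(lib: ModelLibrary, manifest: str | Path) -> None:
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for m in lib:
            writer.writerow([m.model_id, m.domain_acc, m.model_type, m.clade, m.consensus])


def load_clan_map(path: str | Path) -> dict[str, str]:
    """Parse a clan table: domain_acc TAB clan_acc, extra columns ignored."""
    clan_map: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise LibraryError(f"clan table line lacks a clan column: {line!r}")
            if parts[1]:
                clan_map[parts[0]] = parts[1]
    return clan_map


def models_for_domain(
    lib: ModelLibrary, domain_acc: str
) -> tuple[Optional[DomainModel], list[DomainModel]]:
    """Return (SCM or None, CCMs sorted by model_id) for a domain.

    An unknown accession yields ``(None, [])`` rather than an error.
    """
    scm = None
    ccms: list[DomainModel] = []
    for m in lib:
        if m.domain_acc != domain_acc:
            continue
        if m.model_type == "SCM":
            scm = m
        else:
            ccms.append(m)
    return scm, ccms
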