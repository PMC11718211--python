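"""Date TE invasions from time-series presence/absence and trace transfers.

A TE invasion in a species is bracketed by the latest sampled year in which
the TE is absent and the earliest year in which it is present (copy number
> 1).  A lone early present-strain surrounded by later absences is flagged
as a putative contamination outlier and ignored for the window.  Across
species, the direction of horizontal transfer is reconstructed with an
explicit rule engine combining invasion timing, a contact graph (range
overlap or hybridization between species), and shared TE-internal SNPs:
several shared segregating variants indicate transfer of multiple TE
copies (hybridization-compatible), while a single founder variant is the
signature of one horizontal-transfer event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence
import warnings

import pandas as pd
from scipy import stats

from .shortread_quant import CopyNumberEstimate, TESnp


@dataclass
class StrainSample:
    strain: str
    species: str
    year: int
    location: str = "unknown"
    copy_numbers: dict[str, CopyNumberEstimate] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 1800 <= self.year <= 2100:
            raise ValueError(f"implausible collection year {self.year}")

    def present(self, te: str) -> bool:
        return self.copy_numbers[te].present


@dataclass
class InvasionWindow:
    species: str
    te: str
    last_absent_year: int | None
    first_present_year: int | None
    outliers: list[str] = field(default_factory=list)
    status: str = "undated"  # not_invaded | invaded | undated


@dataclass
class TransferEvent:
    donor: str
    recipient: str
    te: str
    year_range: tuple[int | None, int | None]
    evidence: frozenset[str]  # subset of {time_order, contact, shared_snps, hybridization}


@dataclass
class ContactGraph:
    """Undirected species contact: range overlap and/or hybridization."""

    edges: dict[frozenset[str], str] = field(default_factory=dict)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, str]]) -> "ContactGraph":
        g = cls()
        for a, b, kind in edges:
            if a == b:
                raise ValueError(f"self-edge on {a!r}")
            if kind not in ("range_overlap", "hybridization"):
                raise ValueError(f"unknown contact type {kind!r}")
            key = frozenset((a, b))
            # hybridization is the stronger relation; keep it on duplicates
            if g.edges.get(key) != "hybridization":
                g.edges[key] = kind
        return g

    def contact(self, a: str, b: str) -> str | None:
        return self.edges.get(frozenset((a, b)))


def infer_invasion_window(
    samples: Sequence[StrainSample],
    te: str,
    outlier_gap_years: int = 10,
    min_intervening_absent: int = 2,
) -> InvasionWindow:
    """Bracket the invasion between the last absent and first present year.

    A present-sample is a contamination-style outlier iff the next-oldest
    present sample is more than ``outlier_gap_years`` later and at least
    ``min_intervening_absent`` absent samples fall in between.  After outlier
    removal, last_absent_year is the newest absent year older than the first
    present year.
    """
    if len({s.year for s in samples}) < 2:
        warnings.warn("all samples share one year; invasion window undated")
        species = samples[0].species if samples else ""
        return InvasionWindow(species, te, None, None, status="undated")
    species = samples[0].species
    ordered = sorted(samples, key=lambda s: s.year)
    present = [s for s in ordered if s.present(te)]
    absent = [s for s in ordered if not s.present(te)]
    outliers: list[str] = []
    kept = list(present)
    changed = True
    while changed and len(kept) > 1:
        changed = False
        first, nxt = kept[0], kept[1]
        gap_absents = [a for a in absent if first.year < a.year < nxt.year]
        if nxt.year - first.year > outlier_gap_years and len(gap_absents) >= min_intervening_absent:
            outliers.append(first.strain)
            kept = kept[1:]
            changed = True
    if not kept:
        return InvasionWindow(
            species, te, None, None, outliers=outliers, status="not_invaded"
        )
    first_present = kept[0].year
    older_absent = [a.year for a in absent if a.year < first_present]
    last_absent = max(older_absent) if older_absent else None
    return InvasionWindow(
        species,
        te,
        last_absent_year=last_absent,
        first_present_year=first_present,
        outliers=outliers,
        status="invaded",
    )


def cooccurrence(
    presence: pd.DataFrame, te_a: str, te_b: str
) -> tuple[float, float | None]:
    """Joint presence/absence of two TEs across strains.

    ``presence`` is a strains x TEs boolean frame.  Returns the concordance
    (fraction of strains with equal presence state) and the two-sided Fisher
    exact p-value of the 2x2 table; p is None when either TE is constant.
    """
    if len(presence) < 4:
        raise ValueError("need >= 4 strains")
    a = presence[te_a].astype(bool)
    b = presence[te_b].astype(bool)
    concordance = float((a == b).mean())
    if a.nunique() < 2 or b.nunique() < 2:
        return concordance, None
    table = pd.crosstab(a, b).reindex(
        index=[False, True], columns=[False, True], fill_value=0
    )
    _odds, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
    return concordance, float(p)


def shared_te_snps(
    snps_a: Sequence[TESnp],
    snps_b: Sequence[TESnp],
    require_allele_match: bool = False,
) -> list[tuple[TESnp, TESnp]]:
    """SNPs shared between two species: same consensus position (and same
    minor allele when ``require_allele_match``)."""
    tes_a = {s.te for s in snps_a}
    tes_b = {s.te for s in snps_b}
    if tes_a and tes_b and tes_a != tes_b:
        raise ValueError(f"SNP lists are on different TEs: {tes_a} vs {tes_b}")
    by_pos = {s.pos: s for s in snps_b}
    out = []
    for s in snps_a:
        other = by_pos.get(s.pos)
        if other is None:
            continue
        if require_allele_match and s.minor != other.minor:
            continue
        out.append((s, other))
    return out


def reconstruct_cascade(
    windows: Mapping[tuple[str, str], InvasionWindow],
    contacts: ContactGraph,
    shared_snp_counts: Mapping[tuple[str, str, str], int] | None = None,
    multi_variant_threshold: int = 1,
) -> tuple[list[TransferEvent], list[tuple[str, str]]]:
    """Greedy earliest-first assignment of a donor to every invaded species.

    ``windows`` maps (species, te) to its invasion window and
    ``shared_snp_counts`` maps (species_a, species_b, te) (unordered pair) to
    the number of shared TE SNPs.  For each te, every invaded recipient is
    linked to the contact-connected invaded donor whose first_present_year is
    earliest and not later than the recipient's; candidate donors sharing
    more than ``multi_variant_threshold`` SNPs with the recipient outrank
    hybridization contacts, which outrank range overlap.  Recipients with no
    eligible donor are returned as unresolved (external or unsampled donor).
    """
    shared_snp_counts = shared_snp_counts or {}

    def snps_between(a: str, b: str, te: str) -> int:
        return max(
            shared_snp_counts.get((a, b, te), 0), shared_snp_counts.get((b, a, te), 0)
        )

    events: list[TransferEvent] = []
    unresolved: list[tuple[str, str]] = []
    tes = sorted({te for (_sp, te) in windows})
    for te in tes:
        invaded = [
            w
            for (sp, t), w in windows.items()
            if t == te and w.status == "invaded" and w.first_present_year is not None
        ]
        invaded.sort(key=lambda w: (w.first_present_year, w.species))
        for rec in invaded:
            candidates = []
            for don in invaded:
                if don.species == rec.species:
                    continue
                if don.first_present_year > rec.first_present_year:
                    continue
                kind = contacts.contact(don.species, rec.species)
                if kind is None:
                    continue
                n_shared = snps_between(don.species, rec.species, te)
                rank = (
                    0
                    if n_shared > multi_variant_threshold
                    else 1
                    if kind == "hybridization"
                    else 2
                )
                candidates.append((rank, don.first_present_year, don.species, don, kind, n_shared))
            if not candidates:
                unresolved.append((rec.species, te))
                continue
            candidates.sort()
            _rank, _year, _name, donor, kind, n_shared = candidates[0]
            evidence = {"contact"}
            if kind == "hybridization":
                evidence.add("hybridization")
            if n_shared > multi_variant_threshold:
                evidence.add("shared_snps")
            if donor.first_present_year < rec.first_present_year:
                evidence.add("time_order")
            events.append(
                TransferEvent(
                    donor=donor.species,
                    recipient=rec.species,
                    te=te,
                    year_range=(rec.last_absent_year, rec.first_present_year),
                    evidence=frozenset(evidence),
                )
            )
    return events, unresolved


def geographic_patchiness(
    samples: Sequence[StrainSample], te: str
) -> tuple[dict[str, str], bool]:
    """Classify sampling locations as fixed-present / fixed-absent / mixed.

    A patchy distribution (some locations all-present, others all-absent) is
    a hallmark of an ongoing or geographically limited invasion.
    """
    groups: dict[str, list[bool]] = {}
    for s in samples:
        groups.setdefault(s.location, []).append(s.present(te))
    if len(groups) < 2:
        raise ValueError("need >= 2 location groups")
    classes = {}
    for loc, states in groups.items():
        if all(states):
            classes[loc] = "fixed_present"
        elif not any(states):
            classes[loc] = "fixed_absent"
        else:
            classes[loc] = "mixed"
    vals = set(classes.values())
    patchy = "fixed_present" in vals and "fixed_absent" in vals
    return classes, patchy


# --- tabular interchange ---------------------------------------------------


def samples_from_frames(
    sheet: pd.DataFrame, copynum: pd.DataFrame
) -> list[StrainSample]:
    """Join a sample sheet (strain_id, species, year, location) with a
    copy-number table (strain, te, copy_number) into StrainSample objects."""
    samples = []
    for _, row in sheet.iterrows():
        cns = {}
        sub = copynum[copynum["strain"] == row["strain_id"]]
        for _, c in sub.iterrows():
            cns[c["te"]] = CopyNumberEstimate(
                strain=row["strain_id"],
                te=c["te"],
                copy_number=float(c["copy_number"]),
                te_mean_depth=float(c.get("te_mean_depth", 0.0)),
                scg_mean_depths=[],
            )
        samples.append(
            StrainSample(
                strain=row["strain_id"],
                species=row["species"],
                year=int(row["year"]),
                location=str(row.get("location", "unknown")),
                copy_numbers=cns,
            )
        )
    return samples


def windows_to_frame(windows: Iterable[InvasionWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [w.species for w in windows],
            "te": [w.te for w in windows],
            "last_absent_year": [w.last_absent_year for w in windows],
            "first_present_year": [w.first_present_year for w in windows],
            "status": [w.status for w in windows],
            "outliers": [",".join(w.outliers) for w in windows],
        }
    )


def events_to_frame(events: Iterable[TransferEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "donor": [e.donor for e in events],
            "recipient": [e.recipient for e in events],
            "te": [e.te for e in events],
            "year_lo": [e.year_range[0] for e in events],
            "year_hi": [e.year_range[1] for e in events],
            "evidence": ["+".join(sorted(e.evidence)) for e in events],
        }
    )
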