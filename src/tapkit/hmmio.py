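"""Reading HMMER3 domain tables and profile metadata; GA/coverage filtering.

The annotation pipeline starts from the per-domain tabular output
(``--domtblout``) of ``hmmsearch`` run with a proteome as target and a
profile-HMM library as query. Each record is one domain match. Domain
presence is decided by two per-profile cutoffs:

* the gathering (GA) threshold — the suggested minimum bit score a
  match must reach to count as presence of the domain;
* optionally a coverage threshold — the minimum fraction of the
  profile's model length the match must span (used for short or
  promiscuous profiles where a high-scoring partial match is not
  evidence of the full domain).

Both comparisons are inclusive: a score or coverage exactly at the
cutoff passes, consistent with GA being a suggested *minimum*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Union

__all__ = [
    "DomainHit",
    "ProfileMeta",
    "ProfileLibrary",
    "parse_domain_table",
    "parse_profile_metadata",
    "compute_coverage",
    "filter_hits",
    "write_domain_table",
]

PathLike = Union[str, Path]


class DomainTableError(ValueError):
    """Malformed domain-table or profile-metadata input."""


class ProfileConfigError(KeyError):
    """A hit references a profile missing from the library, or a profile lacks a GA threshold."""


@dataclass(frozen=True)
class DomainHit:
    """One profile-vs-protein domain match.

    Coordinates are 1-based inclusive, as printed by HMMER.
    ``domain_ievalue`` is the independent per-domain E-value, used
    downstream to rank competing family candidates; filtering itself
    uses the per-domain bit score against the profile's GA threshold.
    """

    protein_id: str
    domain: str
    full_seq_evalue: float
    domain_ievalue: float
    domain_score: float
    hmm_from: int
    hmm_to: int
    ali_from: int
    ali_to: int

    def __post_init__(self) -> None:
        if self.full_seq_evalue <= 0 or self.domain_ievalue <= 0:
            raise ValueError(
                f"E-values must be strictly positive (hit {self.protein_id}/{self.domain})"
            )
        if not (1 <= self.hmm_from <= self.hmm_to):
            raise ValueError(
                f"invalid model coordinates {self.hmm_from}..{self.hmm_to} "
                f"(hit {self.protein_id}/{self.domain})"
            )
        if not (1 <= self.ali_from <= self.ali_to):
            raise ValueError(
                f"invalid alignment coordinates {self.ali_from}..{self.ali_to} "
                f"(hit {self.protein_id}/{self.domain})"
            )


@dataclass(frozen=True)
class ProfileMeta:
    """Per-profile model length and cutoffs.

    ``ga_threshold`` may be None when the metadata source does not
    carry a GA line; it must then be supplied by configuration before
    :func:`filter_hits` is used. ``coverage_threshold`` is optional
    and lies in [0, 1] when present.
    """

    domain: str
    model_length: int
    ga_threshold: float | None = None
    coverage_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.model_length < 1:
            raise ValueError(f"model_length must be >= 1 for profile {self.domain!r}")
        if self.coverage_threshold is not None and not (0.0 <= self.coverage_threshold <= 1.0):
            raise ValueError(
                f"coverage_threshold must be in [0,1] for profile {self.domain!r}"
            )


@dataclass
class ProfileLibrary:
    """A set of profiles keyed by unique domain name."""

    profiles: dict[str, ProfileMeta] = field(default_factory=dict)

    def add(self, meta: ProfileMeta) -> None:
        if meta.domain in self.profiles:
            raise DomainTableError(f"duplicate profile name {meta.domain!r}")
        self.profiles[meta.domain] = meta

    def __getitem__(self, domain: str) -> ProfileMeta:
        return self.profiles[domain]

    def __contains__(self, domain: str) -> bool:
        return domain in self.profiles

    def __len__(self) -> int:
        return len(self.profiles)

    def with_thresholds(
        self,
        ga: Mapping[str, float] | None = None,
        coverage: Mapping[str, float] | None = None,
    ) -> "ProfileLibrary":
        """Return a copy with GA/coverage thresholds overridden per domain."""
        out = ProfileLibrary()
        for name, meta in self.profiles.items():
            out.add(
                ProfileMeta(
                    domain=name,
                    model_length=meta.model_length,
                    ga_threshold=(ga or {}).get(name, meta.ga_threshold),
                    coverage_threshold=(coverage or {}).get(name, meta.coverage_threshold),
                )
            )
        return out


# domtblout columns (0-based): 0 target, 3 query/profile, 5 qlen,
# 6 full E-value, 12 i-Evalue, 13 domain score, 15-16 hmm coords,
# 17-18 ali coords. 23+ whitespace-separated fields per record.
_DOMTBL_MIN_FIELDS = 23


def parse_domain_table(path: PathLike) -> list[DomainHit]:
    """Parse a HMMER3 ``--domtblout`` file into :class:`DomainHit` records.

    Comment lines (``#``) and blank lines are skipped; records are
    returned in file order. Raises :class:`DomainTableError` naming
    the offending line on malformed records.
    """
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split()
            if len(fields) < _DOMTBL_MIN_FIELDS:
                raise DomainTableError(
                    f"{path}:{lineno}: expected >= {_DOMTBL_MIN_FIELDS} fields, got {len(fields)}"
                )
            try:
                hit = DomainHit(
                    protein_id=fields[0],
                    domain=fields[3],
                    full_seq_evalue=float(fields[6]),
                    domain_ievalue=float(fields[12]),
                    domain_score=float(fields[13]),
                    hmm_from=int(fields[15]),
                    hmm_to=int(fields[16]),
                    ali_from=int(fields[17]),
                    ali_to=int(fields[18]),
                )
            except ValueError as exc:
                raise DomainTableError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_domain_table(hits: Iterable[DomainHit], path: PathLike) -> None:
    """Write hits as a valid ``--domtblout`` file (inverse of :func:`parse_domain_table`).

    Columns both sides represent round-trip exactly; the remaining
    domtblout columns are filled with placeholders.
    """
    with open(path, "w") as fh:
        fh.write("# target name\t...\n")
        for h in hits:
            fields = [
                h.protein_id,  # 0 target name
                "-",  # 1 target accession
                str(max(h.ali_to, 1)),  # 2 tlen (placeholder)
                h.domain,  # 3 query name
                "-",  # 4 query accession
                str(h.hmm_to),  # 5 qlen (placeholder >= hmm_to)
                f"{h.full_seq_evalue:.3g}",  # 6 full E-value
                f"{h.domain_score:.2f}",  # 7 full score (placeholder)
                "0.0",  # 8 full bias
                "1",  # 9 dom number
                "1",  # 10 of
                f"{h.domain_ievalue:.3g}",  # 11 c-Evalue (placeholder)
                f"{h.domain_ievalue:.3g}",  # 12 i-Evalue
                f"{h.domain_score:.2f}",  # 13 dom score
                "0.0",  # 14 dom bias
                str(h.hmm_from),  # 15
                str(h.hmm_to),  # 16
                str(h.ali_from),  # 17
                str(h.ali_to),  # 18
                str(h.ali_from),  # 19 env from
                str(h.ali_to),  # 20 env to
                "0.90",  # 21 acc
                "-",  # 22 description
            ]
            fh.write(" ".join(fields) + "\n")


def _parse_metadata_tsv(path: PathLike) -> ProfileLibrary:
    lib = ProfileLibrary()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) < 2:
                raise DomainTableError(
                    f"{path}:{lineno}: expected domain<TAB>length[<TAB>GA[<TAB>coverage]]"
                )
            try:
                length = int(fields[1])
                ga = float(fields[2]) if len(fields) > 2 and fields[2] not in ("", "-") else None
                cov = float(fields[3]) if len(fields) > 3 and fields[3] not in ("", "-") else None
            except ValueError as exc:
                raise DomainTableError(f"{path}:{lineno}: {exc}") from exc
            lib.add(ProfileMeta(fields[0], length, ga, cov))
    return lib


def _parse_metadata_hmm(path: PathLike) -> ProfileLibrary:
    """Read NAME/LENG/GA header fields from a HMMER3 ASCII profile file."""
    lib = ProfileLibrary()
    name: str | None = None
    leng: int | None = None
    ga: float | None = None
    with open(path) as fh:
        for line in fh:
            tok = line.split()
            if not tok:
                continue
            if tok[0] == "NAME":
                name = tok[1]
            elif tok[0] == "LENG":
                leng = int(tok[1])
            elif tok[0] == "GA":
                # "GA  <seq> <dom>;" — the domain-level cutoff is the second value
                ga = float(tok[2].rstrip(";")) if len(tok) > 2 else float(tok[1].rstrip(";"))
            elif tok[0] == "//":
                if name is None:
                    raise DomainTableError(f"{path}: profile record without NAME")
                if leng is None:
                    raise DomainTableError(f"{path}: profile {name!r} missing LENG")
                lib.add(ProfileMeta(name, leng, ga))
                name, leng, ga = None, None, None
    if name is not None:  # unterminated final record
        if leng is None:
            raise DomainTableError(f"{path}: profile {name!r} missing LENG")
        lib.add(ProfileMeta(name, leng, ga))
    return lib


def parse_profile_metadata(path: PathLike) -> ProfileLibrary:
    """Load a :class:`ProfileLibrary` from a TSV sheet or HMMER3 ASCII profile file.

    The TSV dialect is ``domain<TAB>model_length[<TAB>GA[<TAB>coverage]]``;
    HMMER3 ASCII files are recognised by their ``HMMER3`` leader and read
    via their NAME/LENG/GA header lines. A profile without a GA line is
    recorded with ``ga_threshold=None`` and must be completed (e.g. via
    :meth:`ProfileLibrary.with_thresholds`) before filtering.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("HMMER3"):
        return _parse_metadata_hmm(path)
    return _parse_metadata_tsv(path)


def compute_coverage(hit: DomainHit, meta: ProfileMeta) -> float:
    """Fraction of the profile's model length spanned by the hit.

    coverage = (hmm_to - hmm_from + 1) / model_length, in [0, 1].
    """
    if hit.domain != meta.domain:
        raise ValueError(f"hit domain {hit.domain!r} does not match profile {meta.domain!r}")
    if hit.hmm_to > meta.model_length:
        raise ValueError(
            f"hmm_to={hit.hmm_to} exceeds model_length={meta.model_length} "
            f"for profile {meta.domain!r}"
        )
    return (hit.hmm_to - hit.hmm_from + 1) / meta.model_length


def filter_hits(hits: Iterable[DomainHit], library: ProfileLibrary) -> list[DomainHit]:
    """Keep hits passing the GA score and (where configured) coverage cutoffs.

    Both comparisons are inclusive (>=). Order is preserved; multiple
    surviving hits of one domain on one protein are all retained.
    Raises :class:`ProfileConfigError` for a hit whose domain is not in
    the library or whose profile lacks a GA threshold.
    """
    kept: list[DomainHit] = []
    for hit in hits:
        if hit.domain not in library:
            raise ProfileConfigError(f"no profile metadata for domain {hit.domain!r}")
        meta = library[hit.domain]
        if meta.ga_threshold is None:
            raise ProfileConfigError(f"profile {hit.domain!r} has no GA threshold configured")
        if hit.domain_score < meta.ga_threshold:
            continue
        if meta.coverage_threshold is not None:
            if compute_coverage(hit, meta) < meta.coverage_threshold:
                continue
        kept.append(hit)
    return kept
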