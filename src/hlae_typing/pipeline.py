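"""End-to-end glue: run all three callers over samples and tally cohorts."""

from __future__ import annotations

from typing import Iterable, Sequence

from .allele_db import AlleleDB
from .assoc import GenotypeCounts
from .errors import InputError
from .genotype import GG, GT, TT, UNKNOWN, GenotypeCall
from .sbt import call_site_genotype, type_sample
from .signals import (
    DEFAULT_MAX_DISTANCE,
    DEFAULT_MIN_REPLICATES,
    DEFAULT_MIN_SIGNAL,
    HRMReference,
    call_endpoint,
    call_hrm,
    normalize_melt,
    replicate_consensus,
)
from .synthetic import (
    DEFAULT_CENTROIDS,
    DEFAULT_POST_WINDOW,
    DEFAULT_PRE_WINDOW,
    SimulatedSample,
)


def call_sample_all_methods(
    sample: SimulatedSample,
    db: AlleleDB,
    references: Sequence[HRMReference],
    site_label: str = "NT-26",
    centroids: dict = DEFAULT_CENTROIDS,
    min_signal: float = DEFAULT_MIN_SIGNAL,
    max_distance: float = DEFAULT_MAX_DISTANCE,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
    pre_window: tuple[float, float] = DEFAULT_PRE_WINDOW,
    post_window: tuple[float, float] = DEFAULT_POST_WINDOW,
    verify_typing: bool = True,
) -> dict[str, GenotypeCall]:
    """Genotype one simulated sample by SBT, TaqMan endpoint, and HRM.

    The SBT route runs the full allele-pair ranking (when ``verify_typing``)
    before reading the site genotype from the consensus; HRM wells are
    normalized, called individually and merged under the replicate rule.
    """
    site = db.site(site_label)
    if sample.consensus is None or sample.endpoint is None or not sample.melt_wells:
        raise InputError(f"sample {sample.sample_id!r} lacks simulated readouts")
    if verify_typing:
        type_sample(db, sample.consensus)  # full ranking; raises on bad input
    sbt_call = call_site_genotype(sample.consensus, site)
    taqman_call = call_endpoint(
        sample.endpoint, centroids, min_signal=min_signal, site_label=site_label
    )
    well_calls = [
        call_hrm(
            normalize_melt(w, pre_window, post_window),
            references,
            max_distance=max_distance,
            site_label=site_label,
        )
        for w in sample.melt_wells
    ]
    hrm_call = replicate_consensus(well_calls, min_replicates=min_replicates)
    return {"SBT": sbt_call, "TAQMAN": taqman_call, "HRM": hrm_call}


def counts_from_genotypes(genotypes: Iterable[str], label: str) -> GenotypeCounts:
    """Tally a stream of genotype strings into cohort counts (UNKNOWN dropped)."""
    tally = {GG: 0, GT: 0, TT: 0}
    for g in genotypes:
        if g == UNKNOWN:
            continue
        if g not in tally:
            raise InputError(f"unexpected genotype {g!r}")
        tally[g] += 1
    return GenotypeCounts(label=label, n_GG=tally[GG], n_GT=tally[GT], n_TT=tally[TT])
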