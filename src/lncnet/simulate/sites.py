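"""Planting miRNA binding sites and precursor hairpins with known rule fate.

Each planted site is constructed base-by-base from a per-position state
design (WC / GU / MM plus an optional target-side bulge), so its expectation
score and its eTM verdict are known exactly. After every edit the host is
re-scanned with the production duplex and eTM engines; if the edit created
any alignment outside the planted window (a second, unintended site) the
placement is retried at a different position.

Rule-class designs (positions are miRNA positions, 1 = 5' end):

    target            MM at position 5; expectation 2.0 -> target hit, not eTM
    etm               one of three variants, all satisfying the eTM criteria
    near_miss_seed    single MM inside positions 2-8 -> eTM rejected
    near_miss_budget  MM at 9,10,11,12 (4 edits, expectation 8) -> neither
    near_miss_bulge   3-nt bulge after position 5 -> eTM rejected (position)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..mirna import (
    ETM_BULGE_POSITIONS,
    DuplexAlignment,
    duplex_scan,
    etm_scan,
    local_alignment_identity,
    pair_state,
    position_weight,
    state_penalty,
)
from .config import SimulationConfig
from .truth import PRECURSOR_COLUMNS, SITE_COLUMNS
from .genome import random_seq

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}
_MIRNA_LENGTH_WEIGHTS = {20: 0.15, 21: 0.45, 22: 0.20, 23: 0.10, 24: 0.10}


def make_mirnas(config: SimulationConfig, rng: np.random.Generator) -> dict[str, str]:
    """Mature miRNA set, lengths in 20-24 nt with mode 21."""
    lo, hi = config.mirna_len_range
    lengths = [length for length in range(lo, hi + 1)]
    weights = np.array(
        [_MIRNA_LENGTH_WEIGHTS.get(length, 0.1) for length in lengths]
    )
    weights = weights / weights.sum()
    mirnas = {}
    for i in range(config.n_mirnas):
        length = int(rng.choice(lengths, p=weights))
        mirnas[f"miR{i + 1:03d}"] = random_seq(rng, length)
    return mirnas


@dataclass
class SiteDesign:
    states: list[str]          # per miRNA position, "WC" | "GU" | "MM"
    bulge_pos: int             # 0 = no bulge
    bulge_len: int
    etm_expected: bool

    def expectation(self) -> float:
        total = sum(
            position_weight(p) * state_penalty(s)
            for p, s in enumerate(self.states, start=1)
        )
        if self.bulge_len:
            total += self.bulge_len * 0.5 * position_weight(self.bulge_pos)
        return total


def design_site(
    rule_class: str, mirna_len: int, rng: np.random.Generator
) -> SiteDesign:
    states = ["WC"] * mirna_len
    if rule_class == "target":
        states[4] = "MM"
        return SiteDesign(states, 0, 0, etm_expected=False)
    if rule_class == "etm":
        variant = int(rng.integers(0, 3))
        if variant == 0:  # two non-seed mismatches, no bulge
            states[13] = "MM"
            states[15] = "MM"
            return SiteDesign(states, 0, 0, etm_expected=True)
        k = int(rng.choice(ETM_BULGE_POSITIONS))
        if variant == 1:  # clean 3-nt bulge, expectation exactly 3.0
            return SiteDesign(states, k, 3, etm_expected=True)
        states[13] = "MM"  # bulge + one extra edit (expectation > 3)
        return SiteDesign(states, k, 3, etm_expected=True)
    if rule_class == "near_miss_seed":
        states[int(rng.integers(2, 9)) - 1] = "MM"
        return SiteDesign(states, 0, 0, etm_expected=False)
    if rule_class == "near_miss_budget":
        for p in (9, 10, 11, 12):
            states[p - 1] = "MM"
        return SiteDesign(states, 0, 0, etm_expected=False)
    if rule_class == "near_miss_bulge":
        return SiteDesign(states, 5, 3, etm_expected=False)
    raise ValueError(f"unknown rule class {rule_class!r}")


def _mismatch_base(mirna_base: str, rng: np.random.Generator) -> str:
    options = [
        b
        for b in "ACGT"
        if pair_state(mirna_base, b) == "MM"
    ]
    return str(rng.choice(options))


def build_site_sequence(
    mirna: str, design: SiteDesign, rng: np.random.Generator
) -> str:
    """Target-site sequence (5'->3') realizing the designed states.

    The site pairs the miRNA 5'->3' against itself read 3'->5'; bases are
    emitted 3'->5' while walking miRNA positions, then reversed. GU states
    fall back to MM when the miRNA base has no wobble partner (A or C).
    """
    bases_3to5 = []
    for p, state in enumerate(design.states, start=1):
        mb = mirna[p - 1]
        if state == "WC":
            bases_3to5.append(_COMPLEMENT[mb])
        elif state == "GU":
            if mb == "G":
                bases_3to5.append("T")
            elif mb == "T":
                bases_3to5.append("G")
            else:
                design.states[p - 1] = "MM"
                bases_3to5.append(_mismatch_base(mb, rng))
        else:
            bases_3to5.append(_mismatch_base(mb, rng))
        if design.bulge_len and p == design.bulge_pos:
            bases_3to5.extend(random_seq(rng, design.bulge_len))
    return "".join(reversed(bases_3to5))


def _hits_outside(
    hits: list[DuplexAlignment], start: int, end: int
) -> list[DuplexAlignment]:
    return [h for h in hits if h.end <= start or h.start >= end]


def plant_mirna_sites(
    sequences: dict[str, str],
    kinds: dict[str, str],
    mirnas: dict[str, str],
    plan: list[tuple[str, str, str]],
    rng: np.random.Generator,
    position_ranges: dict[str, tuple[int, int]] | None = None,
    max_attempts: int = 50,
    orf_threshold: int | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Plant one site per (host, miRNA, rule_class) plan entry.

    Hosts may appear once each; the site replaces a same-length stretch of
    the host so sequence lengths are preserved. ``position_ranges``
    restricts the replaced window for a host (e.g. to a 3' UTR); with
    ``orf_threshold`` set, edits that create an ORF of that many codons in
    a lncRNA host are retried elsewhere. Raises when a collision-free
    placement cannot be found.

    Returns the edited sequence map and a truth table of planted sites.
    """
    position_ranges = position_ranges or {}
    edited = dict(sequences)
    rows = []
    seen_hosts = set()
    for host_id, mirna_id, rule_class in plan:
        if host_id in seen_hosts:
            raise ValueError(f"host {host_id!r} used twice in the planting plan")
        seen_hosts.add(host_id)
        mirna = mirnas[mirna_id]
        host = edited[host_id]
        check_orf = orf_threshold is not None and kinds.get(host_id) != "mRNA"
        placed = False
        for _ in range(max_attempts):
            # redraw the whole site each attempt: unlucky random bulge bases
            # can admit an alternative alignment of the same window
            design = design_site(rule_class, len(mirna), rng)
            site = build_site_sequence(mirna, design, rng)
            lo, hi = position_ranges.get(host_id, (5, len(host) - 5))
            hi = min(hi, len(host)) - len(site)
            if hi <= lo:
                raise ValueError(
                    f"host {host_id!r} too short to receive a {rule_class} site"
                )
            pos = int(rng.integers(lo, hi + 1))
            candidate = host[:pos] + site + host[pos + len(site):]
            if check_orf:
                from ..discovery import longest_orf

                if longest_orf(candidate) >= orf_threshold:
                    continue
            scan_hits = duplex_scan(
                mirna, candidate, mirna_id=mirna_id, target_id=host_id
            )
            etm_hits = etm_scan(
                mirna, candidate, mirna_id=mirna_id, target_id=host_id
            )
            if _hits_outside(scan_hits, pos, pos + len(site)):
                continue
            if _hits_outside(etm_hits, pos, pos + len(site)):
                continue
            target_expected = design.expectation() <= 3.0
            if bool(scan_hits) != target_expected:
                continue
            if bool(etm_hits) != design.etm_expected:
                continue
            edited[host_id] = candidate
            rows.append(
                {
                    "mirna_id": mirna_id,
                    "host_id": host_id,
                    "host_kind": kinds.get(host_id, "lncRNA"),
                    "rule_class": rule_class,
                    "start": pos,
                    "end": pos + len(site),
                    "bulge_pos": design.bulge_pos,
                    "bulge_len": design.bulge_len,
                    "expectation": design.expectation(),
                    "target_expected": target_expected,
                    "etm_expected": design.etm_expected,
                }
            )
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place a {rule_class} site for {mirna_id} in "
                f"{host_id} without collision after {max_attempts} attempts"
            )
    return edited, pd.DataFrame(rows, columns=SITE_COLUMNS)


def make_hairpins(config: SimulationConfig, rng: np.random.Generator) -> dict[str, str]:
    return {
        f"hairpin{i + 1:03d}": random_seq(rng, config.hairpin_length)
        for i in range(config.n_hairpins)
    }


def _substitute(seq: str, positions: list[int], rng: np.random.Generator) -> str:
    out = list(seq)
    for pos in positions:
        out[pos] = str(rng.choice([b for b in "ACGT" if b != seq[pos]]))
    return "".join(out)


def plant_precursors(
    sequences: dict[str, str],
    hairpins: dict[str, str],
    host_ids: list[str],
    decoy_host_ids: list[str],
    rng: np.random.Generator,
    max_attempts: int = 50,
    orf_threshold: int | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Insert hairpin copies into lncRNA hosts with controlled identity.

    Positive hosts get a copy with 2 substitutions (identity ~0.978 against
    the reference); decoy hosts get 10 evenly spread substitutions
    (identity ~0.889). Each planting is verified against the production
    local-alignment caller and re-drawn on failure.
    """
    edited = dict(sequences)
    rows = []
    hairpin_ids = sorted(hairpins)
    for role, hosts in (("positive", host_ids), ("decoy", decoy_host_ids)):
        for j, host_id in enumerate(hosts):
            hid = hairpin_ids[j % len(hairpin_ids)]
            hairpin = hairpins[hid]
            n_sub = 2 if role == "positive" else 10
            placed = False
            for _ in range(max_attempts):
                if role == "positive":
                    positions = sorted(
                        rng.choice(len(hairpin), n_sub, replace=False).tolist()
                    )
                else:
                    step = len(hairpin) // n_sub
                    positions = [step // 2 + i * step for i in range(n_sub)]
                copy = _substitute(hairpin, positions, rng)
                host = edited[host_id]
                if len(host) < len(copy) + 10:
                    raise ValueError(f"host {host_id!r} too short for a hairpin copy")
                pos = int(rng.integers(5, len(host) - len(copy) - 5))
                candidate = host[:pos] + copy + host[pos + len(copy):]
                if orf_threshold is not None:
                    from ..discovery import longest_orf

                    if longest_orf(candidate) >= orf_threshold:
                        continue
                identity, coverage, _ = local_alignment_identity(candidate, hairpin)
                hit = identity > 0.90 and coverage >= 0.80
                expected_hit = role == "positive"
                if hit != expected_hit:
                    continue
                edited[host_id] = candidate
                rows.append(
                    {
                        "lncrna_id": host_id,
                        "hairpin_id": hid,
                        "n_substitutions": n_sub,
                        "planted_identity": (len(hairpin) - n_sub) / len(hairpin),
                        "expected_hit": expected_hit,
                    }
                )
                placed = True
                break
            if not placed:
                raise RuntimeError(
                    f"could not plant a {role} hairpin copy into {host_id}"
                )
    return edited, pd.DataFrame(rows, columns=PRECURSOR_COLUMNS)
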