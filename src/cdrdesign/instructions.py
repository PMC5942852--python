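"""CDR Instruction File: a small text dialect for run customization.

One directive per line::

    <CDR|ALL> <FIELD> <VALUES...>

with '#' comments.  Fields: GRAFTDESIGN on/off, SEQDESIGN on/off,
STRATEGY profile/conservative/none, LENGTHS <ints>, CLUSTERS <ids>,
SPECIES <names>, GERMLINES <names>, EXCLUDE_PDBS <ids>, KINK_ONLY
on/off, MINPROTOCOL none/greedy_min/relax_lite, WEIGHT <float>.
``ALL`` expands a per-CDR field to all six CDRs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .database import CdrSetFilter
from .errors import DirectiveError
from .model import CDR_REGIONS

_FIELDS = {"GRAFTDESIGN", "SEQDESIGN", "STRATEGY", "LENGTHS", "CLUSTERS",
           "SPECIES", "GERMLINES", "EXCLUDE_PDBS", "KINK_ONLY",
           "MINPROTOCOL", "WEIGHT"}


@dataclass(frozen=True)
class Directive:
    cdrs: tuple
    field: str
    values: tuple


def parse_instructions(text: str) -> list:
    """Parse instruction text into a directive list."""
    directives = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise DirectiveError(f"line {lineno}: too few tokens: {raw!r}")
        target = parts[0].upper()
        field = parts[1].upper()
        if field not in _FIELDS:
            raise DirectiveError(f"line {lineno}: unknown field {field!r}")
        if target == "ALL":
            cdrs = CDR_REGIONS
        elif target in CDR_REGIONS:
            cdrs = (target,)
        else:
            raise DirectiveError(f"line {lineno}: unknown CDR {target!r}")
        directives.append(Directive(cdrs=tuple(cdrs), field=field,
                                    values=tuple(parts[2:])))
    return directives


def _onoff(directive: Directive) -> bool:
    if len(directive.values) != 1 or directive.values[0].lower() not in (
            "on", "off", "true", "false"):
        raise DirectiveError(
            f"{directive.field} expects on/off, got {directive.values}")
    return directive.values[0].lower() in ("on", "true")


def apply_instructions(directives, filter_: CdrSetFilter, config):
    """Apply directives; returns a new (CdrSetFilter, ProtocolConfig).

    The inputs are not modified.
    """
    filter_ = replace(filter_,
                      include_lengths=dict(filter_.include_lengths),
                      include_clusters=dict(filter_.include_clusters),
                      include_species=list(filter_.include_species),
                      include_germlines=list(filter_.include_germlines),
                      exclude_source_pdbs=list(filter_.exclude_source_pdbs))
    graft = set(config.graft_design_cdrs)
    seq = set(config.seq_design_cdrs)
    weights = dict(config.cdr_weights)
    strategy_by_cdr = dict(config.seq_strategy_by_cdr)
    min_protocol = config.min_protocol
    for d in directives:
        if d.field == "GRAFTDESIGN":
            (graft.update if _onoff(d) else graft.difference_update)(d.cdrs)
        elif d.field == "SEQDESIGN":
            (seq.update if _onoff(d) else seq.difference_update)(d.cdrs)
        elif d.field == "STRATEGY":
            value = d.values[0].lower() if d.values else ""
            if value not in ("profile", "conservative", "none"):
                raise DirectiveError(f"bad STRATEGY {d.values}")
            for cdr in d.cdrs:
                strategy_by_cdr[cdr] = value
        elif d.field == "LENGTHS":
            try:
                lengths = [int(v) for v in d.values]
            except ValueError as exc:
                raise DirectiveError(f"bad LENGTHS {d.values}") from exc
            for cdr in d.cdrs:
                filter_.include_lengths[cdr] = lengths
        elif d.field == "CLUSTERS":
            for cdr in d.cdrs:
                filter_.include_clusters[cdr] = list(d.values)
        elif d.field == "SPECIES":
            filter_.include_species.extend(d.values)
        elif d.field == "GERMLINES":
            filter_.include_germlines.extend(d.values)
        elif d.field == "EXCLUDE_PDBS":
            filter_.exclude_source_pdbs.extend(d.values)
        elif d.field == "KINK_ONLY":
            filter_ = replace(filter_, kink_only=_onoff(d))
        elif d.field == "MINPROTOCOL":
            value = d.values[0].lower() if d.values else ""
            if value not in ("none", "greedy_min", "relax_lite"):
                raise DirectiveError(f"bad MINPROTOCOL {d.values}")
            min_protocol = value
        elif d.field == "WEIGHT":
            try:
                w = float(d.values[0])
            except (IndexError, ValueError) as exc:
                raise DirectiveError(f"bad WEIGHT {d.values}") from exc
            for cdr in d.cdrs:
                weights[cdr] = w
    config = replace(config,
                     graft_design_cdrs=tuple(sorted(graft)),
                     seq_design_cdrs=tuple(sorted(seq)),
                     cdr_weights=weights,
                     seq_strategy_by_cdr=strategy_by_cdr,
                     min_protocol=min_protocol)
    return filter_, config
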