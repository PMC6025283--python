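"""Worked-example inputs: annual publication counts, 1993-2017, for a
PubMed search on immunotherapy, cancer and the tumor microenvironment.

This printed series is the package's reference input for the lifetime
computation: with Y_last = 2016 (2017 being incomplete at retrieval time),
three-year windows and the eligibility threshold of 10, it yields five
Time Periods (2002-2004 ... 2014-2016) and a 15-year lifetime.
"""

from __future__ import annotations

ANNUAL_COUNTS: dict[int, int] = {
    2017: 186,
    2016: 395,
    2015: 325,
    2014: 235,
    2013: 197,
    2012: 163,
    2011: 110,
    2010: 68,
    2009: 48,
    2008: 45,
    2007: 54,
    2006: 27,
    2005: 14,
    2004: 12,
    2003: 14,
    2002: 8,
    2001: 4,
    2000: 4,
    1999: 5,
    1998: 10,
    1997: 0,
    1996: 1,
    1995: 2,
    1994: 5,
    1993: 3,
}

#: Term-funnel sizes reported for the same search: retrieved publications,
#: initial MeSH terms over the lifetime, terms left after routine removal,
#: and the final emerging set.
CASE_STUDY_FUNNEL: dict[str, int] = {
    "publications": 1935,
    "initial_terms": 1758,
    "after_routine_removal": 1644,
    "emerging_terms": 266,
}

#: In the co-occurrence-mode network over the 266 emerging terms, the
#: query term "Tumor Microenvironment" is directly linked to 198 nodes.
HUB_DEGREE: dict[str, int] = {"nodes": 266, "hub_degree": 198}


def percentage(part: float, whole: float) -> float:
    """Share of ``part`` in ``whole`` as a percentage, rounded to one
    decimal — the display convention of the run report."""
    if whole == 0:
        raise ValueError("whole must be nonzero")
    return round(100.0 * part / whole, 1)
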