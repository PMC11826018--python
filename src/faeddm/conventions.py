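"""Shared design constants and naming conventions.

The single place where the response-boundary convention lives: the *upper*
diffusion boundary is a "male" response, the lower boundary a "female"
response.  Signed reaction times are positive for male and negative for
female responses.  Every other module imports these names rather than
restating them.
"""

from __future__ import annotations

# Boundary convention: upper = male, lower = female.
UPPER_BOUNDARY = "male"
LOWER_BOUNDARY = "female"

#: Choice codes used in array computations: +1 upper/male, -1 lower/female.
CHOICE_UPPER = 1
CHOICE_LOWER = -1

#: Group labels: autistic and neurotypical participants.
GROUP_AUT = "AUT"
GROUP_NT = "NT"
GROUPS = (GROUP_AUT, GROUP_NT)

#: Adaptor conditions (which face preceded each test-face block).
ADAPTOR_ANDRO = "androgynous"
ADAPTOR_MALE = "male"
ADAPTORS = (ADAPTOR_ANDRO, ADAPTOR_MALE)

#: Morph levels: percentage of "male" in the test-face morph.
MORPH_LEVELS = (20, 40, 60, 80)

#: Trial-table CSV schema (exact column order).
TRIAL_COLUMNS = (
    "participant_id",
    "group",
    "adaptor",
    "morph_pct",
    "trial_index",
    "response",
    "rt_ms",
)

#: Response codes in trial tables.
RESPONSE_MALE = "male"
RESPONSE_FEMALE = "female"
RESPONSE_OMITTED = "omitted"


def choice_code(response: str) -> int:
    """Map a response label to its signed choice code (+1 male, -1 female)."""
    if response == RESPONSE_MALE:
        return CHOICE_UPPER
    if response == RESPONSE_FEMALE:
        return CHOICE_LOWER
    raise ValueError(f"response {response!r} has no boundary code")


class DomainError(ValueError):
    """A parameter or observation lies outside its mathematical domain."""


class ConfigError(ValueError):
    """An invalid configuration value."""
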