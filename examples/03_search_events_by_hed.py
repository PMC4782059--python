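"""Select events by hierarchical tag without any external code table.

HED tags are slash-delimited paths; a query matches every event whose
annotation contains a tag with that prefix, so coarse queries select
whole families of events.
"""

from esskit.hed import parse_hed_string, parse_hed_tag, search_event_instances
from esskit.model import EventInstance

ding = parse_hed_string(
    "Sensory Presentation/Auditory/Ding, Participant/Effect/Auditory, "
    "Participant/Effect/Cognitive/Expected"
)
buzz = parse_hed_string(
    "Sensory Presentation/Auditory/Buzz, Participant/Effect/Auditory, "
    "Participant/Effect/Cognitive/Oddball/Target"
)
events = [
    EventInstance("ding", 1.0, ding),
    EventInstance("buzz", 2.5, buzz),
    EventInstance("ding", 3.1, ding),
    EventInstance("buzz", 7.8, buzz),
]

for query in (
    "Participant/Effect/Cognitive/Oddball",   # only the rare targets
    "Sensory Presentation/Auditory",          # every auditory stimulus
    "participant/effect/cognitive/expected",  # case-insensitive
):
    hits = search_event_instances(events, parse_hed_tag(query))
    print(f"{query:42s} -> {[e.code for e in hits]}")

# The oddball query returns only the two buzz events; the auditory query
# returns all four; matching ignores case throughout.
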