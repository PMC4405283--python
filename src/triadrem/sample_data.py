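"""A small example fragment of a proximity-logger stream.

Six encounters between two collared steers over roughly twelve minutes of
one evening, in the exact dialect the parser expects: focal animal,
encountered animal, day-first start/end timestamps, and the logger's own
duration column in seconds.  Used in the documentation and as a parsing
fixture; the manifest below places the fragment in a triad whose third
(unfamiliar) animal has not yet recorded any contact.
"""

from datetime import datetime

from .logger_io import TriadManifest

SAMPLE_LOGGER_TEXT = """\
Cow ID,Encountered cow ID,Start date,Start time,End date,End time,Duration (seconds)
1,2,9/03/2009,18:49:34,9/03/2009,18:49:35,1
1,2,9/03/2009,18:52:57,9/03/2009,18:56:00,183
1,2,9/03/2009,18:56:05,9/03/2009,18:56:21,16
1,2,9/03/2009,18:56:48,9/03/2009,18:58:38,110
1,2,9/03/2009,18:56:05,9/03/2009,18:56:21,16
1,2,9/03/2009,19:01:03,9/03/2009,19:01:06,3
"""

#: Durations as printed in the stream above, in row order.
SAMPLE_DURATIONS = (1, 183, 16, 110, 16, 3)


def sample_manifest() -> TriadManifest:
    """Manifest for the sample fragment: animals 1 and 2 are the familiar
    residents, animal 3 the unfamiliar introduction; time zero is the first
    recorded encounter."""
    return TriadManifest(
        triad_id="sample",
        id_map={"1": 1, "2": 2, "3": 3},
        introduction=datetime(2009, 3, 9, 18, 49, 34),
    )
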