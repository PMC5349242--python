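"""The five signal classes used throughout the pipeline.

Bright-field dual-colour ISH shows the gene probe as a small black
(silver) dot and the chromosome-10 centromeric reference probe (CEP10)
as a small red dot.  A detection is classified as one of:

* ``PTEN``  -- black gene signal
* ``CEP10`` -- red centromeric signal
* ``MIXED`` -- co-located gene + centromere signal
* ``WHITE`` -- white background noise (discarded downstream)
* ``BLUE``  -- hematoxylin-stained cell material (discarded downstream)
"""

PTEN = "PTEN"
CEP10 = "CEP10"
MIXED = "MIXED"
WHITE = "WHITE"
BLUE = "BLUE"

#: canonical ordering of the five classes
CLASSES = (PTEN, CEP10, MIXED, WHITE, BLUE)

#: classes that represent true hybridization signals
SIGNAL_CLASSES = (PTEN, CEP10, MIXED)

#: classes discarded before ratio computation
REJECT_CLASSES = (WHITE, BLUE)
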