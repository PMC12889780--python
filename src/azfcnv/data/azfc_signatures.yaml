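# AZFc copy-number signature catalog.
#
# Reference copy numbers per amplicon/IR class and the integer copy vectors
# that define the recognized architectures.  The gr/gr deletion removes one
# green and two red amplicon copies (taking two of the four DAZ gene copies
# with it); the distinct-breakpoint gr/gr subtypes produce this same dosage
# vector and are therefore indistinguishable by copy number.  The OTHER_CNV
# entries are rarer AZFc rearrangements whose carriers are excluded from
# gr/gr association testing.
#
# This file is editable configuration: vectors were transcribed once from
# published architecture diagrams and can be revised without code changes.
classes:
  ctrl:
    reference_copies: 1
    is_control: true
  teal:
    reference_copies: 2
  blue:
    reference_copies: 4
  green:
    reference_copies: 3
  red:
    reference_copies: 4
  gray:
    reference_copies: 2
  yellow:
    reference_copies: 2
  ir1:
    reference_copies: 2
  ir2:
    reference_copies: 2

signatures:
  - name: reference
    category: REFERENCE
    copy_vector: {teal: 2, blue: 4, green: 3, red: 4, gray: 2, yellow: 2, ir1: 2, ir2: 2}
  - name: grgr_deletion
    category: GRGR_DEL
    copy_vector: {teal: 2, blue: 4, green: 2, red: 2, gray: 2, yellow: 2, ir1: 2, ir2: 2}
  - name: b2b3_deletion
    category: OTHER_CNV
    copy_vector: {teal: 2, blue: 3, green: 2, red: 2, gray: 2, yellow: 2, ir1: 2, ir2: 2}
  - name: b2b4_deletion
    category: OTHER_CNV
    copy_vector: {teal: 2, blue: 2, green: 0, red: 0, gray: 2, yellow: 2, ir1: 2, ir2: 1}
  - name: grgr_duplication
    category: OTHER_CNV
    copy_vector: {teal: 2, blue: 4, green: 4, red: 6, gray: 2, yellow: 2, ir1: 2, ir2: 2}
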