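>seed01
KNERERRRKIRYERLRRSRAFAKLLEVLRFNSKTDKANMLDEAIEYLKELQRQVQ
>seed02
ANERERRRKIRNERLRRSRMFAKLLLESPFGSKTDKASMLLEAIWYLKELQRQVE
>seed03
ANERERRRKQRNERLRRSRIFATLLEELVFGWKTDKASMLDEAIEYLKELTRQVQ
>seed04
AWERERRRKIRNERLRRSRAFAKLLEEIPFGVKTDIARMLDEAIEYLKELQRQVQ
>seed05
ANERERRRKIRRERLRRSRAFAKLLEELWFGDKTMKASMLDEVIEYLKELQEQVQ
>seed06
ANERERRRKIRNERLRRQRAFAKLLEELPFYSKTDVGSALDEAIEYLKELQRQGQ
>seed07
ANERERRRKIRNERLRRSWAFAKLLEELPFGSKTTKASMLDWAIESLKELQRFKQ
>seed08
ANERERRRKIRNERLRRSRAFDKLLEYLYQGSKTDKASMVMEAIEYLKELQRQVQ
>seed09
INERERRRKIRNERLRRIAAFAKLLEELPFLSKTDKASMLDEAIEYLKELQNQVQ
>seed10
ANERERRRKIRNERLRRSRAFAKVLEELPFESKTDKSMMLDEAIEYAKELQHQVQ
>seed11
ANERERRRKIRNERLRRSRAFAKLLEELPFGSKTVKAWVLDEAVTYLKELARQVQ
>seed12
ANERERRRKTRNERLRRSIAFACLLRELPFGMKTDKASMLDEAAEYLKELQRQVQ
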