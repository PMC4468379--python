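>ref_I synthetic exemplar group=I
TEGVMVQSDNMVKPCKIETKYPPQKYQRCWPTVFHAIGVCWANHTETEMTRRIIGSGYYM
NNPCPNYTTRQCIYMFVCEVQHDAFEMAEHPNYMTWTQCMNGNLCGYADCFFAHYRVFSL
DGNTPLHLAARNGHLEVVKLLLEAGADVNARDKDGNTPLHLAARNGHLEVVKLLLEAGAD
VNARDKDGNTPLHLAARNGHLEVVKLLLEAGADVNARDKQELGKDYFQHVQEVWWNEFW
>ref_IIa synthetic exemplar group=II subgroup=IIa
TELTAQTMRFFKFIYPIGYLYMNWSPLVLWCLKAGPCAFLWYHQPPDCLYLHFGSAYVRR
PMSPNIYMSAACSLTAWEMCYDRSMCDNMHVRFEIAQHPGRVLWNPCTTWYECMWIACFF
AHNYGTQRQYIKFAFWVDPMPQIYMQQFCLSTRDWTVNWAAAGGFNAPERAIWNTQPFPA
TYVAIIDQTIVTESVFPQPDQQTTIRVWEAQFNWKGLQDKEQTKKN
>ref_IIb synthetic exemplar group=II subgroup=IIb
NSWEFTQRYWVSKQFSSRLKLAVNKKIFSCGFIVMHQDISCTPVHIEDFSWRRENEVEQY
DSWSCGVISVNQVCFAMFWCVLIHSMFEDRSHPDTPVVRICLSDFNCYSTFCFFAHNRKT
WKESYERTWDDYDEPLSFWFSCMAIIRLCYVWGKFEAMDEVMFQGNGNQNKTVFED
>ref_III synthetic exemplar group=III
TGTRQYLLRTIQFNSCRAYMLRNRDNNWKPYYCYGFRYHVFSNCMNPHWTASIIRRQYDN
GWYMVVDCSTVYSVSICVRRYSCIIIHEDFESTEHPLWVQYIVCWQEGNCGDEYCFFAHA
LQNDPFFVFLSRNTMPTRQKNKSKMSMITKVTLRAKVPNQRPLFHHLYILKPYVKGVMRD
VIMFLTTMSLKNFIRSCSTLCRGQKQGM
>ref_IV synthetic exemplar group=IV
EMALEGTFPKLTEWWQAQPSKFNWCQEFDYHIGVICFGLHDQMYTLRRSTFEEAYITTLC
NTWGRQQCTTLSACIFGHWMFEDNDHPELMFQNECTELEYCGVYFCFFAHFYVDIATWYP
QRPYPIMARRLVSIDEFILWGWRVKATGETR
>ref_V synthetic exemplar group=V
IDFGECMFSWGPMDEVMTCPVVANKSDGKFTFCFGSWSHGSRMCEITHNDWNIARRPPEV
NDYFGSSCTQWIPQLMRVWGSSWCQFSELCNSEHREFELEAHPIYPSFFWCSNGVMCAVM
MCFFAHTMLYIAKEDNYPQIPSPTNFPMEPTENSKGKNRNDTWDGEVWAIFMWDEMNSL
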