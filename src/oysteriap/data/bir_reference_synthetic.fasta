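>consensus synthetic BIR backbone, canonical numbering 1-90
FVKDVMSDEAQCTECKYNTHALPVVTLTEPGNPGFYPWDMMFEAFTVNVLSSLAAKCFICECFVMQEATGFELKGEHPNWSKDCKFNLKL
>Dm_DIAP_BIR_ref synthetic stand-in
FVKDVMSDEAQCTERKYNTHALPVVTLTEPGLPGFYPWDMMFEAFTVNVLSCLAAKCFICHCFVMQEATGFELKGEHPNWSKDCKFNLKL
>Hs_BIRC_BIR_ref synthetic stand-in
FVKRVMSLEAQCTECKYNTHALPVVTLTEPGNPGVYPWDMMFEAFTVNVLSSLAEKCFICECFVMQEATGFELKGEHPNWSKDCKFNLKL
>Mm_BIRC_BIR_ref synthetic stand-in
FIKDVMSDEAQCTECKYNTHALPVVTLTEPGNPGFYPWDDMFEAFTVNVLSSLANKCFICECFNMQEATGFELKGEHPNWSKDCKFNLKL
>Dr_BIRC_BIR_ref synthetic stand-in
FVKDVMSDEAQCTEAKYNTHALPVVTLTEPGNPGFYPWDGMFEAFTVNVLSSTAAKCFICECFVKQEATGFELKGEHPNWSKDCKFNLKL
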