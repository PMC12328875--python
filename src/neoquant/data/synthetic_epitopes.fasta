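>SYN_EPI_001 synthetic epitope (randomly generated stand-in)
QISYNTSRQ
>SYN_EPI_002 synthetic epitope (randomly generated stand-in)
LFMIFAMLD
>SYN_EPI_003 synthetic epitope (randomly generated stand-in)
EKGRMFICQ
>SYN_EPI_004 synthetic epitope (randomly generated stand-in)
LKKSPIMG
>SYN_EPI_005 synthetic epitope (randomly generated stand-in)
PYEGCLEVQ
>SYN_EPI_006 synthetic epitope (randomly generated stand-in)
SNVWVQDHWK
>SYN_EPI_007 synthetic epitope (randomly generated stand-in)
KVEHRVQAIL
>SYN_EPI_008 synthetic epitope (randomly generated stand-in)
CIKYNWHDC
>SYN_EPI_009 synthetic epitope (randomly generated stand-in)
QQMWWERTGL
>SYN_EPI_010 synthetic epitope (randomly generated stand-in)
CTWDIDLQY
>SYN_EPI_011 synthetic epitope (randomly generated stand-in)
NLGCGTLYI
>SYN_EPI_012 synthetic epitope (randomly generated stand-in)
MLGFDAAHG
>SYN_EPI_013 synthetic epitope (randomly generated stand-in)
LDFWRIFVP
>SYN_EPI_014 synthetic epitope (randomly generated stand-in)
CEWAANDAK
>SYN_EPI_015 synthetic epitope (randomly generated stand-in)
GCAWFAHCP
>SYN_EPI_016 synthetic epitope (randomly generated stand-in)
PLGYPDPED
>SYN_EPI_017 synthetic epitope (randomly generated stand-in)
HSAPRMPIYK
>SYN_EPI_018 synthetic epitope (randomly generated stand-in)
CIYFCQWWQ
>SYN_EPI_019 synthetic epitope (randomly generated stand-in)
DNDYVKLEV
>SYN_EPI_020 synthetic epitope (randomly generated stand-in)
PRVTFVDH
>SYN_EPI_021 synthetic epitope (randomly generated stand-in)
AKEPWTNFR
>SYN_EPI_022 synthetic epitope (randomly generated stand-in)
HTNVQRRNW
>SYN_EPI_023 synthetic epitope (randomly generated stand-in)
KQNDRVLVSC
>SYN_EPI_024 synthetic epitope (randomly generated stand-in)
VIFMIMSTNI
>SYN_EPI_025 synthetic epitope (randomly generated stand-in)
HHDMAIFEFR
>SYN_EPI_026 synthetic epitope (randomly generated stand-in)
QYLWTGHNPC
>SYN_EPI_027 synthetic epitope (randomly generated stand-in)
YNVLIFNRH
>SYN_EPI_028 synthetic epitope (randomly generated stand-in)
AQLPCFFPE
>SYN_EPI_029 synthetic epitope (randomly generated stand-in)
AWAESGRIV
>SYN_EPI_030 synthetic epitope (randomly generated stand-in)
NHGGPALA
>SYN_EPI_031 synthetic epitope (randomly generated stand-in)
KEIVVSYDFM
>SYN_EPI_032 synthetic epitope (randomly generated stand-in)
LVNDYLEGF
>SYN_EPI_033 synthetic epitope (randomly generated stand-in)
GCEKFLQMA
>SYN_EPI_034 synthetic epitope (randomly generated stand-in)
RGQYYWTYVV
>SYN_EPI_035 synthetic epitope (randomly generated stand-in)
KGNLVSYIY
>SYN_EPI_036 synthetic epitope (randomly generated stand-in)
NIPMCVTPVT
>SYN_EPI_037 synthetic epitope (randomly generated stand-in)
VINKLRHRRV
>SYN_EPI_038 synthetic epitope (randomly generated stand-in)
CNTMRRFPSA
>SYN_EPI_039 synthetic epitope (randomly generated stand-in)
YTFWFVNIA
>SYN_EPI_040 synthetic epitope (randomly generated stand-in)
TRKNNMPWFD
>SYN_EPI_041 synthetic epitope (randomly generated stand-in)
PLRCCCFEDW
>SYN_EPI_042 synthetic epitope (randomly generated stand-in)
ERAKDISLNE
>SYN_EPI_043 synthetic epitope (randomly generated stand-in)
SIRRYNPCPN
>SYN_EPI_044 synthetic epitope (randomly generated stand-in)
RKTVPAPFPT
>SYN_EPI_045 synthetic epitope (randomly generated stand-in)
CICITEDVH
>SYN_EPI_046 synthetic epitope (randomly generated stand-in)
KNTISHIME
>SYN_EPI_047 synthetic epitope (randomly generated stand-in)
WFRGFAIQS
>SYN_EPI_048 synthetic epitope (randomly generated stand-in)
EGLAMDEYG
>SYN_EPI_049 synthetic epitope (randomly generated stand-in)
RECIPRFK
>SYN_EPI_050 synthetic epitope (randomly generated stand-in)
HVLMPYHD
>SYN_EPI_051 synthetic epitope (randomly generated stand-in)
MIAHPGPLVM
>SYN_EPI_052 synthetic epitope (randomly generated stand-in)
NPSWPKGA
>SYN_EPI_053 synthetic epitope (randomly generated stand-in)
ERMVPTAMF
>SYN_EPI_054 synthetic epitope (randomly generated stand-in)
CNRKGACNT
>SYN_EPI_055 synthetic epitope (randomly generated stand-in)
DGYRWTECW
>SYN_EPI_056 synthetic epitope (randomly generated stand-in)
CCETTSMQ
>SYN_EPI_057 synthetic epitope (randomly generated stand-in)
EQNKKIANPI
>SYN_EPI_058 synthetic epitope (randomly generated stand-in)
RSQAWAKCE
>SYN_EPI_059 synthetic epitope (randomly generated stand-in)
PASRSWGCT
>SYN_EPI_060 synthetic epitope (randomly generated stand-in)
KFLDQDEAF
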