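>CEG001
MHKIFAFEDIGKTKFGYPRGAATFRAYWWKDSLDDVVQLFMDVVITLVHFMMLMGIWRMN
QFNGLMNIMHNWYPENDHWVIALFHPNWNGLQPEARPNTGGNESVVRLYTFWWDVLVLRS
GNFMDMIHDRYASYRKLADGEKNATDSNVVSSHIDFPPLPYETMGYAHLNAAYDFVGKLA
LSMLYYIHPGKTFWQMPSHKEQTPLKLDGSYLPTAFAKDMWYGIYWEFDHLMIQQNDQDG
TQIRARNFNTRMGDVEVFS
>CEG002
MSNGKKAVVGEYFSQSMSYHKHEKRRRPVKVLMKDAWVLQFNTNMHGVLFHRDGKPQLYI
MDTNLKFVHIKKRKLSDLSWPPKAVGFYPSNKLGTWEYGEKRMMWWGSGDGNTPRNGEKT
VSATTGWKNYSNRPDNRYPNPVVLTYISTQLMRKVIKHSDNSHDTHPDGLRTHKEHGNRY
KGAHVINMRVGMDYDREIMQPTRWYIWYQHLNQFFIPPN
>CEG003
MYVIWNFNMNQLLTIGFSKQDYNQAERYSHDDFRITVLKMSYEVQHFHWYQTMNFGYPSA
FYARPERVLMVNMSNEWSQQMRYNHWDEHDYAMDTGKRGYAVQPYLIIPGNRINSFFKVL
GYYMWRRETYTMHDRNHVTTVNDFSGKNVGRPDIQKFNQTINRMLEQWFVILQWPVYTVY
VFTSYFSPDWHNLPESFPGVRLPISIGPGLGFHNITFAHDDAIAWSHMYLDRMGYPAIYY
L
>CEG004
MRFMSILGDNWWHMTMVVMRKLMMRVVVLHNYKKTISRLNAESLEHRQRKTTDLPYAVQW
QISRQFMYLSKTKMKRRMPFMPASWSTLISHMVMKPWYDAYYVSAAIVTYESVHSGHSSK
MTDVKHYWTTFPNNDLFSKTSYKNFSIKHRYHDKWTVWLDIHHWHQTNMMSHTFTQETTN
VWWTAMMQMIQTFMFFFGGDPHQEYEG
>CEG005
MGFTMRVNRHHHARGDFTQSTSSSWLHPVKMIRQGNIYKFQPTKEQSGWYVRGTDQNMKH
SYWTDSHATIMERWDQVRYWDFMNSAATSHAKGGEVNVFMWQNEMPFIAKGGIYDPANIV
LLWRERNWHYSMYTNHYPFQNAVTETGRSTSMGWSGSQKFHHQMRELMGEGAAVKIIKSI
RNIHWGGMGSVHQTHTVPADNEWDMRQWAEDHSHDFDQYITTSGSVIEEPLGVWQEDLDK
YQAPTPLTMKVVSQV
>CEG006
MEDVEHGFRGAEFPEVMWELMQRMSHPDYEPKILDIRTFIKRERWMFTVNVNRFAYNIDR
RGFGERMKFMVSYMDNEMQRKDVVKDIIYTSMAYEHHGHLLTNMMHTNTKKLQALENLFF
HEEQLRAPDNWDFRLSTFIDGYWPHWVKGKYTWYMERQSQTGITVEIVSIVIDQSNFFFV
KHREYAQRWEDQYFWYHQGKVMVLQEHAGGQGENPMDIDLLNPGVM
>CEG007
MTFDNELPISHFMDYFWKMGMINHSTWETPALGGKFHKHNYYMYYDGETHWFKYDIHQLI
HMYLETKWDRRDENAMIIDTKTWQNQMPNAHTPPAQHTQHKGEDQGEDIVQVKKAADANV
LPKVNATKNANHVLKLYPVSNEMEFRKYTRADHKIRPIAWFMPNMQYRLTPMHNYREKFY
A
>CEG008
MIVRDTEYWNMMMSTGMYGSMRIESNTQPVQGMSRNVYDGWMIHNDIPSTNDYTAWLHAA
HHKPRKYFKSHVPRQDTIVYNVYEFWRQDPNQTQVKGQDTHAFDFYMSHHAIRSNLPEYT
NKHQWAWMSFAMWFHYEPDEGKLGWLWQGSAWIGYDHFVMELIIAFPKQRILNLNYENFP
SLPTGHSSHAISNVTHPMKLTFSTSIHRYD
>CEG009
MMEGELLTAGIRLDWWGEYHGTKWNQKMRVINRMRAQLFQQMNYHVIQFYMDENFTFTKH
WKHAQNQYIGWAVESFWAVDIMMYRFEEFGDLYDPWLILFKYWMLKDIRKMKRMFYITWL
IHTQVIYYTRGIHGATAEMYMPSIPRPDTGFHYHQQILYFFTGKWKSSEVYYATLKYQTN
ETTKIVRYWSH
>CEG010
MLKVNSTPYHQDVIWYHQLAYIWRIAQAKSKQVIYINIFHFIDYGGDTPWKVKQMWVMKY
QPIPLGPSDYQPNSIAFTVDTKLAWAEYLGWAFDIGTARGDWQWTGNYKVMGDAQMWTRG
QNLQSYIPYFQEHLEASMSWDQGHYFFVFYTVATSILKKLMGYDFEILQFSQLYTEDGEP
NKFPTDIRPVRYNIWHLVEPFKTWDQYGWRFFRYQHSLIHTLING
>CEG011
MKFRVSEATQHDTSVHYIHSDWMYWKAWNYNQAGWKIKVLDSWQYVFYKDPFYADMMPMD
YTWKMKAGAGQTRVKEFVEDQLHEWVARNHYAIIQRWPQFFSKDEENGKSQDRKIGFAFV
GTLGGDQFFPVMRNVMPGIQQMDYGDDLGWVKSLTLAREGNMIMGIDEVFITTQLVSTDQ
NDRINMEKVHQWWPYYYLQWMESIYHFWMVVHTIKE
>CEG012
MLWITTQRADITGKGTNGQFMVQAMQSPSKFKIVQNSGDQVDAPHSWWLVFRKDMPDHNS
WFLIFGPKRDKTDYTWWLPAHVYRMYMLGVHFMQSRLDIVYLVGPQGHWNHGWHKGEGRA
WWKWEGKNLGEMQVKENSAVYEAEQIPIGISMLTTRYERRGTQHRHMRMETDALRVHAPD
EVVSMYHVQLNPELSMHITWVSAPSYHHIWTILFPGHNMRVRMMNVTPWDD
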