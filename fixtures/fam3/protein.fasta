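>fam3_g1
TGNIYESVLESSRSVWTRESRKASGLGALKARFLTKTYTAHGGLPRELYQVESTSRGAYQTVSRLHIPRYGSHDCRGVLTLVHFGLFSLDRYRQVSVGLTAEPGHNSPQLTLSPRLQRKVFAIQEQTGCPPKPLPTRQGNIFTTIWTGIFLRDTVGNRYILKLARDRDMPGGRLHRLKGTLSLVIGAVGWVGELRFRLRAYQIRMLLRDPGGIDHHKRFKYIRLPEKEWNWMLDLLDLSELSACGPLCQIKFRNLRSILQRASVLGVYKNRAAIGHTCFLIVRQERLVVRRPPVTFITPI
>fam3_g2
TGNTYESVLESSRSMWTRELRKASGLGALKARFLTKMYTAHGGLPRELYQVECTSRGAYQTVSRLHIPRYGPHDCRGVLTPVHLELFSLDTYRQASVGLTAEPGHHSPQLTSSPRLQRNVFAIQEQTGCPPKPLPTRQGNIFTIIWTGIFVRNTVGNRYMLKLARDRDAPGGRLHRLKGTLSLVIAAVGWVGELRFRLRAYQIRMLLRDPVGIDNHKRFKYIRLPEKEWGWMLDLLDHSEFSACGPLCQIKSRNLRSILQRASVLEVYKNRAAIGHTCFLMVRQKRLDVRRPPVTFITPI
>fam3_g3
TGNTYESVLESSRTMWTRELRIASGLGALKTRFLPKMYTAHGRLPRERYQVESTSRGAYQTVSRLHIPRYGPHDCRGVLTPVHFQLFSLDTYRQVSVSLTAEPGHNLPQLTSSLRLQRKVFAIQVKTGCPPKPVPTRRGNIFTTIWTGIFVRDTVGNRNILKLARDWDRPGGRLHRLKGTLSLVIAAVGWVGELRFRLRAYQIRMLLRDPVGIDNHMRFKYIRLLEKEWDWMLDLLDLSEFSACGPLCQLKSRNLRSILQRASVLGVYKSRTAIGHTCSLMVRQERLVVRRPPVTFITPI
>fam3_g4
TGNTYESVLESSLTMWTSDLTTASSLGALKVRLLTKMYTALGGLPSERSQVESTSRGAYQTVSGLHIPRYGSHDCRGVLTPVHFDLFSLGTYRQVSVSLTAEPGHNSTQLTSILRLQYKVFAIHVQAGCPPKPLPTRQGNTFTTIWTGMFVRDTAGNRYISKLAGDRGTPGGRLHSLNGTLSLVITAVGWVRDLRLRLRAYQIRMLHRDPVGIDNLKRFKYIRLLEKEWDWMLDLLDLSEFSACGPLCLLESRNLRSILRRASVLGVYKSRAAIGHTCFLTVRQGRLVVRRPPVTFLTPI
>fam3_g5
ANDLDAIFLYANRPMCAQECAEVHRHQATTPRIPHNILNGEGRRVRGQNKVERRARGACRRVTRIFIPPRGLPSYHEGWILRRHRLLLFWSYTQVLVSLEAEAPNSTLPLAQKLSLKTNNIGLHKQTGCNPQSPPSRQAKTYKITCKDQFDGATVDKRYILKHDGGKGISENPRYRLWGTLGFYHRPGGGLRGFSVRLRSLHIGLLPQACAEINIYETVKRTCLSETSRMWLLDFTDLSKLYACRHMSQQDTCYLRAIAQRVHDLADQRHRLETGQGCSRMSRQERFVANRPLITLISPD
>fam3_g6
TDDRHAFFLDTNGPLCALECDGVHRLQATTARLPYNMPKADARPVRGQYNVERKPRGAGQRVTMILIPLCGLHSHHEGWILTRHRLFLFRPYRQFPVRLEAGTPNNILRLTQKPRLKTNDFALHVETGSNPHSPLSRQDNISTITCKNLFGRATVNKRYILKRGGGRGISENPRDRLWGTLGLIHMPGGGVRESSVGVRSPHIGLLPQTYAETNIGEQAKRTGLSKSCRVWLLGLTDVSKLYVCGPRSQHEPCYLRTIVPRSHDFGDRKDRSGTGQTCYRTCQQEKFVVRRPLVTLISTF
>fam3_g7
TDDRSAIFLDTNGPLCDIECEVVHRLEATTTRLPLNMPYADERPVRGHHNVERKPRGACQRVTRILIPLCGLPSYHEEWILTRHRLFLFWSYRQFPGRLEAGTPNSILRLTQKLLLKTNDFALYVETGSNPHSPLSRQDNISTITCINLIGRATVNRRCILKRGGGRGISENPRNRLWSTLGSIHMPGGGVRESSVGVRSPHISLLPQTYAETNIDEQAERSGLSPTCRVWLLGLTDLSKLYVCGSGSQQAPFYLRTVVQRGHDFGDRKYRLGTGQTCHRMCQQDRFVVSRPPVTLISMI
>fam3_g8
TDDRSAIFLDTNGPLCDIECEVVHRLEATTTRLPLNMPYADERPVRGHHNVERKPRGACQRVTRILIPLCGLPSYHEEWILTRHRLFLFWSYRQFPGRLEAGTPNSILRLTQKLLLKTNDLALYVETGSNPHSPLSRQDNISTITCINLIGRATVNRRCILKRGGGRGISENPRNRLWSTLGSIHMPGGGVRESSVGVRSPHISLLPQTYAETNIDEQAKRSGLSPTCRVWLLGLTDLSKLYVCGSGFQQAPFYLRTVVQRGHDFEDRKDRLGTGQTCHRMCQQDRFVVSRPPVTPISMI
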