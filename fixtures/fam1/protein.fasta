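>fam1_g1
QTQKRATGDMNRGGGQGDPDEGAKIAAETPFPPGLSVVRNASVSITLQLAAMRFGHFLNLDPGTRDNRLVAGCSHQEVERPVMWSSVELKDAPSPCRPRQQHFNVHVSCGRRGSTPVSSRPPMTRCQRQSLTICHATMWWLVSLSSHSRVLLIGHNVPLLNACRMVQSAARKPRKRRFNNPTEYKVVTHLSALSALPQLGDSTWLGIRNIQATNAAYNREKLDLAIEEPVSPRANSNRYNLRFVAFHDIASKQAWSRLPRAACTTSSCFVRHVVLEALAQYIPGSEKVVQSICKQKASTV
>fam1_g2
QTQKRTIGNMNRCGGHGDPDEGAKIAAETPVPPGLSVERKASVSITLQRAALRYGHYLNLDAGTRDNRLVLGCSHQEIERPLIWWPVELRDVPSPPRPRQLHFNVNVSCGRRGSTPVSSRPPMTQCQRLSLTICHTTMCWRVSLSSHSRELLIGLNVPLLSACRMVQSAARKPRKRRFNNPTEYKVVTHLTALSALLQIGNSTWLGISNIQATNAEYNREKLNLAIEEAVSPRADSDRYNLRFVDCNDIASKQALSRFPRAAWTPSSCFVGHVVLEQLAQYIPGSENVVLSICKQKASTM
>fam1_g3
QTQKRTIGNMNRCGGHGDPDEGAKMAAETPVPPGLSVERNASVSITLQRAALRYGHYLKLDAGTRDNRLVLGCSHQEIERPLIWWPVELRDVPSPPRPRQLHFNVNVSCGRRGSTPVSSRPPMTQCQRQSLTICHATMCWRVSLSSHSRELLIGLDVPLLSACRMVQSAARKPRKRRFNNTTEYKVVTHLTALSALLQIGNSTWLGISNIQATNVEYNREKLNLAIEEAVSPRADSDRYNLRFVDFNDIASKQALSRFPRAAWTTSSCFVGHVVLEELAQYIPGSENVVQSICKQKASTM
>fam1_g4
QTQKRTIGNMNRCGGHGDPDEGAKIAAETPVPPGLSVERSASVSITLQRAALRYGHYLNLDPGTRDNRLVLGCSHQEIERPLIWWPVELKDVPSPPRPRQLHFNVNVSWGRRGSTPVSSRPPMTQCQRQSLTICHATMCWRVSLSSHSRELLTGLNVPLPSACRMVQSAARKPRKRRFNNPTEYKVVTHLTALSALLQIGNSTWLGISNIQATNAEYNWEKLNLAIEEAVSPRADSDRYNLRFVDFTDMASKQALSRFPRAACTTSSCFVGHVVLEELAQYIPGSENVVQSICKQKASTM
>fam1_g5
RTRKRTIGNIHRCRGQGVSTEGGKISPETPVPPGLSVECNASKPVTLQRAALRLGNFPNLDPGTRDYRLVFRRSYQEIVRPVIRSSVELKDAPSPHRRRQLDFIVNVSYGLQGTTPVSSCPPMTHYQRLLPTEYETTMWWRASLSSHSRELSIGLKVPLLSACRMVQSAARRHIKRRSINHKGCKVVTHLTALSALYQIGDSTRPSFSNIQATKAEYFRDVLDLSIKEAVSSRVDSNRSNLRFVEFDDTGSQKVLSRFTRAACTTSSCLVSHVVLEELSQYMPVSEKAEQSICKQTANTM
>fam1_g6
RTRKRTIGNIHRCRGQGVSTEGGKISPETPVPPGLSVECNASKPVTLQRAALRLGNFPNLDPGTRDYRLVFRRSYQEIVRPVIRSSVELKDAPSPHRRRQLDFIVNVSYGLQGTTPVSSCPPMTHYQRLLPTEYETTMWWRASLSSHSRELSIGLKVPLLSACRMVQSAARRHIKRRSINHKGCKVVTHLTALSALYQIGDSTRPSFSNIQATKAEYFRDVLDLSIKEAVSSRVDSNRSNLRFVEFDDTGSQKVLSRFTRAACTTSSCLVSHVVLEELSQYMPVSEKAEQSICKQTANTM
>fam1_g7
QNRKTTIGNMNRCGGQGDSSEADKIVPETPAPPGLFAEGNAVITITLQRAALRPGNFPNLEPGTRDYRLVFGRSHQEIERPVIRSPVEPKDAPSPHRPRQLHLNVNVSYGRRGTTLVSSCPPITQCQRLSLTKCEATMWWRASLPSHSRGLSIDLLVPLLRACRMVQSAARKPIKGQSNNPNECKVVTHLTALSALFQIGNSTPLSFSNTQATKAEHKCDILDLAIKEAVSPRADSNRCNLRFVDFDDIASKEVLSRFTKAACTTSLCLVSHVVLEELAQYMPVSEKAEQSLCKKKASTM
>fam1_g8
QTRKRTIGDMNRCGGQGASPEGAKIVPETPVPPGLSVEGYATISITLQRAALRLGNIPNLDPGTRNHRLVFGRSHKEIERPVIRSPVELGDAPSPHRPRQLHFIVEVSYGRRWTTLVSSCPPMTQCQRLSLTKCEATMWWRTNLSSHSRGPSIDLHVPLLSARRMVQSAARKPTKRQSNNPNECKVVTHLTALSALFQIGDSNRLSFSNIQATKVKLSCDILDWAIKEALSPRTDSNRYNLRFVDFDDLASKGVLSRWTRAACTTSSCLVSHVVLEELAQYMPVSEKAEQSICKQRASTM
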