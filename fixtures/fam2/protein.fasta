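>fam2_g1
ALSPLTYFIYSAWPLAKLYLLGRRFIIHPTLFSNASSHRADGESPRKKCRIMHVYCVNTQNGWFGLWSALRPVLTAFYGMVGTQARVKLDVRLMVHRSEVKVRTGVYRLDASMQNWITTYWGLLSVGGLRTKNISPHLVERVRARYHIGTHAPPGRYEQSVEGSRSSAKPTLTGQAYLRSKTIPHQAQVPHTRTQSRCPKGKRKKPELCRNPLTRRVWGCGLPLFVSFAPQLLLVKQRVRGLFRALLTSFRHNLFRLSQRTLISDTKGHSVNVLTPDLHRSQTYVHKVVRLSSLTKAQID
>fam2_g2
AVSPLTYFIYLAWPLAKLYLLERRFITHPTLVSNAASHRAVGESSRKKYRIMHIYCVNTQNGWFGLWSSLRPVLTAFYGMVRTQARVKLDVRLMVHRSEVKVRTGVCRLDALMQNWITTYWGFLSVGGLRTKNKSLHLVERVRARYRSGTYAPPGRYEQSVEGSRSSAKPTLTGQADLSSKTIPHQALVPHTRTQSRYRKGKRNKPELCRSPLTRRVCGYGLHLAVSFAPQLLLVKQRVPGLFRALLTSSRYNLSRLSQRTLISDTKVHSINVLTSDLHRSQTYVHRVVRLRSLTKAQMN
>fam2_g3
AGRPSMYFIHSGWPTAKLYSLGRRFITYSTLISSAYHHRAAGVNSGYKYQAMHCYPFNTQTGFFGGCSVLCPLLTEFTGKVRAQALAKLNTRLMQLTSKMKLQAVLFRQDALLQDCIASYRGFLNAGVSRTMSVPPDLVNWEKASYLVGTYAHSGRCGRDDKGSQPSAIPALIAQVYASSMTISQLAQVPQTRIQSGHHKGKQNNPRSCRNPLTGHVRRYGSPVALSLAPQLLLVKQRVPGLFRALVTSSCHDGLRRSQRTLISYVKNHSVKALMPDLHRLQTFVNRLLRRCFLIKQRID
>fam2_g4
AGRQFMYFIHSGWPTAKLYSLGRRFITYPSLISSAYRHRVAGVNPTDKYQTMNCYRFNTQNGFFGRCSFLCPLLTEFTGKVRGQALAKLNARLMELTSKMKLQAVRYRQDSLIQDWRASYRGFLNAGVSRTVSVPPNLVNREKASYVVGTYALSGRCGRDDKGSHLSAIPPLIAQVYTSSMTLSHLAQVPHTRIQSGHHKGKRNNPGLCRNHLTGHVWRYGSPVALLFAPQLLLVKQRAPGLLRGLLPSSGHDRLRRSQRTLISHVKNHSVKALMPDLHRLQTFVNRLVRRCFLIKQLID
>fam2_g5
ASRQFMYFIHSGWPTAKLYSLGRRFITYPTLISSAYRHRVAGVNPRDKYQTMNCYRFNTQNGFFGRCSFLCPLLTEFTGKVRGQALAKLNARLMELTSKMKLQAVRYRQDSLIQDWIASYRGFLNAGVSRTMSVPPNLVNREKASYVVGTYALSGRCGRDDKGSQLSAIPPLIAQVDTCSMILSHLAQVPHTRIHSGHHKGKRNNPGLCRNHITGHVWRYGSPVAVSFAPQLLLVKQRVPGLLRALLPSSGHDRLRRSQRTLISHVKNHSVKALMPDLYRLQTFVNRLVRRCFLIKQLID
>fam2_g6
ARRPFIFFIHFAWPRARLYSMGRRFIPYPTLISSAYRHRIDGLSSRDKNQTMHFYRFNTETGFFARCSFLCPLLTEFSGTVRGHAVVKLNARLMDLTRKIKVQAVIYRQDALMRNWIESYRGFLSAGVSRTTIVSPILTKQVKARHIIGMYAHSGRCGRGDKGSQPSATPALIAQAYAGSTTISHLTQVPHSRIQTGHHKRKHNNPELGPHPLTGSFWRYGSPVSLSFAPQLQLVKQRVPGLRGVLLTSLCHGRLGLSQRTLISDIKDHRVKSLIPDLQRSQTYVNRGVRRCFHIKQRID
>fam2_g7
ARRPFMYFIHFAWPRASLYSMRRRFIPYPTLISSAYRHRIAGLNSRDKDQTMHLYRFNTETGFFARFGFLCRLLTEFSGTVRGQAVVKLNARLMDLTWKIKVQAVIYGQDAFMRNWIESYRGFLSAGVSRTSIVSPNLANRVNARDVIGTYALSGRCGRGDKGSQPSAIPALIAQAYASSMTRSHQAQVPHSRIQSGHHDKNHNNPELCPHPLTGSFWRYGSPVALSFAPQLLLVKQRVPGLRGVKLTNLCHGRLRLSQRTLISDVKDHSVKSLIPDLHRSQIYVKRGVQRCFLIEQRID
>fam2_g8
AGRPFIYFLQSAWPPAKLYSLGRRFVTYPTLISSLYRQRVSGINSRDKYQTMYFNRFNTWKEVFGRCSLLCPLLTEFSGTVRGQALVNLNARLMEMTSKIKFQAVIHTQDTLMQNWIVSYRGFLTTCVSRTTSASPNLVKRVKARYRIGTHALSGRCGRGAKGSQPSAIPALLAQAYPSSMTISHKAQVPHTRIQSGHHKGKHNNPESCGNPLTGHVWRYGSPAALSFAPQLLLEKQRVAGLCRALLTSLCHDRRRLSQRTLISYVKVHSVQAFMPDLHLSQTYVNRGLGRFFIIKHRVD
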