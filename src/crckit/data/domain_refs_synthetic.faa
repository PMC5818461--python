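>GAG__gypsy_crm1
GDTEAKQMAGKPTHTGGKVGNLIQHRLKFEFKKVDNGGLADDIQVSKVTNGIETQCGVAG
VGKTSPQEMAWIFDDKPLNTMTVRGLLRVVALVCKCGPDFSLSNGLVIATGCNTKIVHEP
IRLGHGRDRKGLDGKESEEPRMLLIGALPILFVYSGEVGSGETGGFFFAKRPKNPAAGSL
EEDCALSVIRKSDSTRKEVRISVRDSIKVIGWANLLLNVSMFGSCIRNQQQFEDLLIIID
KVKRDEKLELGPTIFEPGELIGGNQRYHKIDRGNGAAGGRLPPNMYPRDDAAREKAKAPM
RDRTFLARKQWTALNLLFGYLYRRVLASSNALILKSVGILDLDAPLAATEENWQVIAKLV
KNYEALGEALLGTRKLVPPIVGKEKSRNRSPADATGQVLA
>PR__gypsy_crm1
SHFLSVIFEEFGRSIPLAPQLEVQSAQENKVGINTTRNRDGEFYCMKAIGIKTGIAEPEM
VMMKVGVADFAIMDNHAEQPASVVVQGTSILAQAFSYPAGRTNGCNKWVKQQYDRVLLEI
>RT__gypsy_crm1
SIWTTGHAMKSERFIQTVSADCKTGDLRALVLPSINAYESEKLTKGAVEMGCGLTTTASF
QIQGLPCVLITDELGEYSDQASRIQACEEMYEKNAMMMGQKDESNTIEERFVNVCTRSGL
SDFKDAHFGSFKHEEVKMESKTSDIMRSYAVTAAMKSCQRATRTTCRFCAGPQALIIIMT
YTSLAGCTGTFSIAGATDPITAISLNTVDLKYMEPRDDSRLMAQFVDHGLIMSCKLNSAL
NFFQGQNRERAILSKAGAVLVISTLQERFE
>RH__gypsy_crm1
MSYAGKETRLASLYSQLGRSDDLITKPDHLAQMHARDRHRGYTVAIAVGALTSEMNAARK
MNSQFLGMTGLNDVLCAKDNPWKARISVIAPEKYRVEDMDNEFQEFENLRLQNFDKKGFA
YTGGRYSFSG
>INT__gypsy_crm1
GGEASMESIVMTMTRDYEGQIPIRATREKLTGELQLYGSFDFADELAVLLDKGGDPKAKV
RGSLGEENGSLDEFSGFSRKILRFYLKRSPAVICNINVTDTCKDAPTSNIHGLTLHGQAL
FASGRYRQLFQDYPLKRNKLLIQRLARRAYEPIDALGTGYNTEQIGAIYGLVALVNDMNV
FLQDVDEAGGLRAGFSFPTHRALDTQGNEQTIGIKDGCEKGRIARRAPSDCSKGVDGWAD
QIFINNTHGTFQSKNVESIPQRPLEILHQSEFLRKHIVLYTVRSAQASGDNLQILIKVVR
>CHROMO__gypsy_crm1
MEMKVQLELLANEVAASPQQLTTAAIEHTYLDGPSDLKKRLHFKSQPLLDVQVIA
>GAG__gypsy_crm2
GQTEAKQMAGFPTQTKGKVGNLIQIRLAFEFKFVDNDGIHMFIQVSKVTNGNETQPGVIG
VVKTSAQEMAWVFDDKPLFTVTVRGLLWVVCLPKAGGPDFSLSSGLVSAELASTKIVVEP
ERLGSGRDGKELIGKESEENRMLAAFALPILFLYSGEVGDGETGGNFTALRLKNPAAVRL
EEACATQVIRNSDERLITVVISIYCSPKVIGWANLLLNSLMFGSCIRLQQQEEDLLIIDD
KVKTDWKLELIRNMFEPGELIGGNILYHKIDRLNGTDGLAKPPNMYCSGDAAREKAELLM
RDRLDLARGQWTALELLFGYLYRRVLASSEALILKSVEILLLRAPYAAPQEGWCVIVPLR
KNYEALGEALLGTRKLNPICVGAEFGRLRSPDEATGAVWA
>RT__gypsy_crm2
SIWTTGHAMKSEQVEQTFAVGCKTGDLRLKVTDGWCMSESEKLTKEAVETGFGKGVAASF
QIQGLPCRLITDELGENSFVVKRIQACEEMYFKNAMLMGQKDESPTIEKRFVNGCTRMGH
LWFKDAHNISFSHEEVKMEPKLSGHMRTFAVRAAKKSCSRATRTTTTDCAGIVALIITDT
YTSLLIVTGVFSIAGATSPITAASLNTVDLKYMEFRDDSRLMAQFVLEKTPVSCLLNQAL
NVFQGQNRKRASLSKASAVLVIITLQERRH
>INT__gypsy_crm2
GGEASMESIKMTMVVDYLGQINIRATREKLTGELQLYCSSDFNLELAVLVDQGGIPKVLV
RGSLGPENGSLDENSGFQRKIGAFYLKRSPAVIDNIHVTDSCKDADTSYIHGLYKLLQAL
DASGLSRHLFQDVPLVYNKKLILREVRRAYAPIDGLSTGYNIEQLEIIYHLCAQSNDMNV
IKQLVDEAGKLYAGFSFPWIRAFDSQGNEQSIPIKDACEKGLIERRALSDIHKGVDRWAD
QVFLNNTRGTFQSINFESAPNRQLRTLHQQEFLRKHIVQYTYLFLARSGDNLQDLIKVHR
>GAG__copia_syn1
LSSDALHIEIRMATVVLCEQILLSVEFKPKSLDNYGDLHGPALQLGGGLDCTWPAERSHA
KPDGPLEPTRAKDLDILLLVPTDFENQTGSYRNNTGEGHKSFRAGIAFIGAGIVPGSQAT
YVEAASRRFKPRRDQASRTRGDDYLRTTEIWLHSDTPVREEHSTQLDNPGQRLSGQGLFK
LYRKDDNLEIGEGTASETDQLHYLVHAHNLEGSSPELEWLVQKPHLAPIKRTAWALHLIR
LSFSKGNLFPKGNQNVDSRIWTQSTPEYKSPLGFFLINMILAWASLTEPDDVGDISNSES
ALSALNAFVRTSRARMPLSVVASQESCFPTKMDNNREIDRVARERSGALIGVCDVAEIIL
SNEELFAIDQGSDRQPGLVLDEVLQLWARSRSSTKIYYTK
>PR__copia_syn1
KSCRGVFILAVTDAGNMKLMKNKPEGKTGLLAQEKNHLNETRSRSATSADLRSKILLTDG
PNVTTINALQGVTDNRDSFEKVQRRGRLSETAEQIDADILAVALYTTDQTSTNANSYAKE
>INT__copia_syn1
PVYGDWGILQKTSAMLEPQAALVLLEVFRRIDRGLILDSISVLFLQERHASGEFHMKFET
PVRYCGIGKDGDFNLASRLKTLIDADKDYAGLDPDPSDKAFGRAVISSRCARTKSKHPIH
AFLSKKADPRLHKLSHGPVDPESEGEEDSTFVQLRQKEKIENSDELYEGGLMQRLAGHKL
LVSETIDVSLQVLLTEGMFMPCAAQRREIGYMEAFEVNTGRNKNLLEDQGDKSQRGVGNR
QLGFRLKATTSQVFVRLALDLPFSLVEGKLELPQRGFNLDFSKRSELDGEARDTWKLTLR
>RT__copia_syn1
MCACPVLERANLHEWRRVQDWESLKPTPQIQSKTFSGPNVGEETKGHNLIERTLNPHSKI
SRSQLSNDRDRVNYSHADRLVFGFEANLNFYAAVAIGNSLAARVYDGRTTVGRGPAQEGK
YMPFKCHMFYGFRAFLPQLIAHHTDVQELVKAVGVAAATFETDGDFSRGHGEFDNPMGEL
IWISLQYVHGANQLNIPFDTTRLRAYYRGALAAQVMPAKGDVCVFGISDRPSSNLHKILG
EWQLGEMGYGRLLSARARRGFTIFDQRRMQ
>RH__copia_syn1
DSYGSAGGILSTKIKGGSLEGFLIQDGCVHEVPKHPPFEASPLTELSRLWACNCSRSPLV
RNYGNVAQTVAILYSMACYKILTPIGRVWESKTRAKKCLNILTVPEDANHALKTQQVNRF
KILRKSPSIE
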